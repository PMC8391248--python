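"""Marker informativeness statistics and panel balancing.

Implements Rosenberg's informativeness for assignment (In), the
population-specific divergence (PSD) of one group against the pooled
remainder, the simple delta allele-frequency differential used for
ranking, cumulative per-group PSD totals over a panel, and a greedy
cumulative-PSD balancing procedure.

All entropies use the natural logarithm, so In is in nats and is bounded
above by ln(K) for K populations (ln 2 for any two-group comparison,
including every PSD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import FrequencyTable

__all__ = [
    "rosenberg_in",
    "population_specific_divergence",
    "delta_differential",
    "divergence_profile",
    "cumulative_psd",
    "balance_panel",
    "BalanceReport",
]


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln p with the 0 * ln 0 := 0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def rosenberg_in(freq_vectors) -> float:
    """Informativeness for assignment over K population frequency vectors.

    ``freq_vectors`` is a (K, A) array of per-population allele-frequency
    simplexes over a common allele set.  Returns

        In = sum_a [ -pbar_a ln pbar_a + (1/K) sum_i p_ia ln p_ia ]

    with pbar the unweighted mean across populations; result in nats,
    0 <= In <= ln K, and In = 0 iff all vectors are equal.
    """
    p = np.asarray(freq_vectors, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("need a (K>=2, A) array of frequency vectors")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each frequency vector must sum to 1")
    pbar = p.mean(axis=0)
    val = float((-_xlogx(pbar) + _xlogx(p).mean(axis=0)).sum())
    return max(val, 0.0)


def population_specific_divergence(freq_vectors, populations: Sequence[str], target: str) -> float:
    """Two-group In between a target population and the pooled remainder.

    The remainder is pooled with equal weight per population (not per
    sample): its vector is the unweighted mean of the other populations'
    frequency vectors.
    """
    populations = list(populations)
    if target not in populations:
        raise ValueError(f"target population {target!r} not present")
    p = np.asarray(freq_vectors, dtype=float)
    if p.shape[0] != len(populations):
        raise ValueError("populations/freq_vectors length mismatch")
    t = populations.index(target)
    others = np.delete(p, t, axis=0)
    if others.shape[0] == 0:
        raise ValueError("need at least one non-target population")
    pooled = others.mean(axis=0)
    return rosenberg_in(np.vstack([p[t], pooled]))


def delta_differential(
    freq_vectors,
    populations: Sequence[str],
    target: str,
    comparator: Sequence[str] | None = None,
) -> float:
    """Delta allele-frequency differential for AIM ranking.

    delta = max over alleles of (p_target,a - mean over comparator
    populations of p_a).  The allele attaining the maximum is the
    "informative allele".  ``comparator=None`` means all other populations;
    SAS-informative SNPs are conventionally ranked against EUR only, and
    Eurasian SNPs against a regional average.
    """
    populations = list(populations)
    if target not in populations:
        raise ValueError(f"target population {target!r} not present")
    if comparator is None:
        comparator = [p for p in populations if p != target]
    comparator = list(comparator)
    if not comparator:
        raise ValueError("comparator set is empty")
    p = np.asarray(freq_vectors, dtype=float)
    t = populations.index(target)
    comp_idx = [populations.index(c) for c in comparator]
    comp_mean = p[comp_idx, :].mean(axis=0)
    return float(np.max(p[t] - comp_mean))


def divergence_profile(freqs: FrequencyTable) -> pd.DataFrame:
    """Per-SNP divergence table: global In, per-group PSD, per-group delta.

    Returns a DataFrame indexed by rsID with columns ``In_global``,
    ``target_group``, ``psd_<group>`` and ``delta_<group>`` for every
    population in the table.
    """
    rows = []
    for j, snp in enumerate(freqs.loci):
        p = freqs.freqs[j]
        row = {
            "snp_id": snp.snp_id,
            "target_group": snp.target_group,
            "In_global": rosenberg_in(p),
        }
        for g in freqs.populations:
            row[f"psd_{g}"] = population_specific_divergence(p, freqs.populations, g)
            row[f"delta_{g}"] = delta_differential(p, freqs.populations, g)
        rows.append(row)
    return pd.DataFrame(rows).set_index("snp_id")


def cumulative_psd(
    freqs: FrequencyTable,
    assignments: Mapping[str, str],
    exclude: Sequence[str] = (),
    assigned_only: bool = True,
) -> dict:
    """Cumulative per-group PSD totals over a panel subset.

    ``assignments`` maps rsID -> target group for the SNPs to accumulate;
    SNPs in ``exclude`` (e.g. a Eurasian-divergent set) are dropped first.

    With ``assigned_only=True`` (the default) each group's total sums the
    PSD of that group over the SNPs assigned to it.  With
    ``assigned_only=False`` each group's total accumulates its PSD over
    *every* retained SNP — the accumulation used for panel-wide balance
    plots, where a marker informative for one group still contributes its
    (smaller) divergence to every other group's running total.
    """
    excluded = set(exclude)
    ids = {snp.snp_id: j for j, snp in enumerate(freqs.loci)}
    groups = sorted(set(assignments.values()))
    totals = {g: 0.0 for g in groups}
    for snp_id, group in assignments.items():
        if snp_id in excluded:
            continue
        j = ids[snp_id]
        p = freqs.freqs[j]
        if assigned_only:
            totals[group] += population_specific_divergence(p, freqs.populations, group)
        else:
            for g in groups:
                totals[g] += population_specific_divergence(p, freqs.populations, g)
    return totals


@dataclass
class BalanceReport:
    """Outcome of the greedy cumulative-PSD balancing procedure."""

    selected: dict  # group -> list of rsIDs
    cumulative_before: dict
    cumulative_after: dict
    iterations: list = field(default_factory=list)

    @property
    def spread(self) -> float:
        vals = list(self.cumulative_after.values())
        return max(vals) - min(vals)


def balance_panel(
    candidates: pd.DataFrame,
    budget: Mapping[str, int],
    protected: Sequence[str] = (),
    initial: Mapping[str, Sequence[str]] | None = None,
) -> BalanceReport:
    """Greedy selection of per-group SNP sets balancing cumulative PSD.

    ``candidates`` is a DataFrame indexed by rsID with a ``target_group``
    column and ``psd_<group>`` columns (as produced by
    :func:`divergence_profile`).  Each group's candidates are the rows
    assigned to it; its score is the candidate's own-group PSD.

    The procedure fills each group to its budget greedily (highest PSD
    first), then hill-climbs: at each step it evaluates every single swap
    (replace one non-protected selected SNP with an unused same-group
    candidate) and applies the one that most reduces the max-min spread
    of cumulative totals, stopping when no swap improves it.
    Deterministic: ties break by ascending rsID.  Protected SNPs are
    never removed.
    """
    groups = list(budget)
    protected = set(protected)
    pools: dict[str, list] = {}
    for g in groups:
        sub = candidates[candidates["target_group"] == g]
        # sort by descending PSD, ascending rsID on ties
        order = sorted(sub.index, key=lambda s: (-sub.loc[s, f"psd_{g}"], s))
        pools[g] = order
        if len(order) < budget[g]:
            raise ValueError(
                f"infeasible budget: group {g} has {len(order)} candidates "
                f"for a budget of {budget[g]}"
            )

    def psd(g, s):
        return float(candidates.loc[s, f"psd_{g}"])

    selected = {g: list(initial.get(g, [])) if initial else [] for g in groups}
    for g in groups:
        for s in pools[g]:
            if len(selected[g]) >= budget[g]:
                break
            if s not in selected[g]:
                selected[g].append(s)

    def totals():
        return {g: sum(psd(g, s) for s in selected[g]) for g in groups}

    before = totals()
    log = []
    while True:
        cur = totals()
        spread = max(cur.values()) - min(cur.values())
        best = None
        for g in groups:
            removable = sorted(
                (s for s in selected[g] if s not in protected), key=lambda s: (psd(g, s), s)
            )
            unused = [s for s in pools[g] if s not in selected[g]]
            for out in removable:
                for inc in unused:
                    trial = cur[g] - psd(g, out) + psd(g, inc)
                    vals = [trial if gg == g else cur[gg] for gg in groups]
                    new_spread = max(vals) - min(vals)
                    if new_spread < spread - 1e-12 and (
                        best is None or new_spread < best[0] - 1e-15
                    ):
                        best = (new_spread, g, out, inc)
        if best is None:
            break
        _, g, out, inc = best
        selected[g].remove(out)
        selected[g].append(inc)
        log.append({"group": g, "removed": out, "added": inc, "spread": best[0]})
    after = totals()
    return BalanceReport(selected, before, after, log)
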