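"""Downstream evaluation computations.

* 10-percentile co-ancestry comparison between two estimation methods,
  with per-component r-squared from a linear regression over individuals;
* detection-threshold summaries for minor co-ancestry components;
* the Evanno delta-K statistic over replicate clustering log-probabilities;
* panel composition auditing (per-group counts, multi-panel overlap);
* diplotype (2-SNP microhaplotype) recoding onto A/C/G/T pseudo-alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PercentileComparison",
    "percentile_compare",
    "detection_summary",
    "EvannoTable",
    "evanno_delta_k",
    "panel_audit",
    "load_bt_panel",
    "diplotype_alphabet",
    "diplotype_encode",
]


# ---------------------------------------------------------------------------
# 10-percentile co-ancestry comparison
# ---------------------------------------------------------------------------


@dataclass
class PercentileComparison:
    """Binned comparison of two sets of co-ancestry estimates.

    ``bin_means_a``/``bin_means_b`` are (10, K) DataFrames of mean
    proportion vectors per percentile bin; ``r2`` maps each component to
    the squared Pearson correlation between the two methods' per-
    individual proportions (the r-squared of an ordinary least-squares
    fit of B on A).
    """

    populations: list
    bin_assignments: pd.Series
    bin_means_a: pd.DataFrame
    bin_means_b: pd.DataFrame
    r2: dict


def _estimates_frame(estimates, populations) -> pd.DataFrame:
    rows = {e.sample_id: [e.q[e.populations.index(p)] for p in populations] for e in estimates}
    return pd.DataFrame.from_dict(rows, orient="index", columns=populations)


def percentile_compare(qa, qb, sort_component: str, n_bins: int = 10) -> PercentileComparison:
    """Compare two co-ancestry estimate sets in percentile bins.

    ``qa`` and ``qb`` are sequences of ``AdmixtureEstimate`` for the same
    samples (method A and method B).  Samples are sorted by method A's
    ``sort_component`` proportion (ties by sample id) and split into
    ``n_bins`` near-equal bins, remainders going to the earliest bins;
    per-bin component means are computed for both methods.  r-squared is
    the squared Pearson correlation per component over individuals.
    """
    pops = list(qa[0].populations)
    A = _estimates_frame(qa, pops)
    B = _estimates_frame(qb, pops)
    if set(A.index) != set(B.index):
        raise ValueError("the two estimate sets cover different samples")
    B = B.loc[A.index]
    n = len(A)
    if n < n_bins:
        warnings.warn(f"only {n} samples for {n_bins} bins; bins of size <= 1", stacklevel=2)
    order = sorted(A.index, key=lambda s: (A.loc[s, sort_component], s))
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    bins = {}
    pos = 0
    for i, size in enumerate(sizes):
        for s in order[pos : pos + size]:
            bins[s] = i
        pos += size
    assignments = pd.Series(bins, name="bin")
    means_a = A.groupby(assignments).mean().reindex(range(n_bins))
    means_b = B.groupby(assignments).mean().reindex(range(n_bins))
    r2 = {}
    for p in pops:
        x, y = A[p].to_numpy(), B[p].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r2[p] = 1.0 if np.allclose(x, y) else float("nan")
        else:
            r2[p] = float(np.corrcoef(x, y)[0, 1] ** 2)
    return PercentileComparison(pops, assignments, means_a, means_b, r2)


def detection_summary(estimates, truth, detect_at: float = 0.05) -> pd.DataFrame:
    """Fraction of individuals whose minor components are detected.

    ``truth`` is a DataFrame (samples x components) of true co-ancestry
    proportions; ``estimates`` a matching sequence of
    ``AdmixtureEstimate``.  For each component, individuals are binned by
    their true proportion (<5%, 5-10%, >=10%) and the fraction with an
    estimated proportion >= ``detect_at`` is reported per bin.  Bins with
    no individuals are NaN.
    """
    pops = list(truth.columns)
    E = _estimates_frame(estimates, pops).loc[truth.index]
    edges = [(0.0, 0.05, "<5%"), (0.05, 0.10, "5-10%"), (0.10, 1.0001, ">=10%")]
    rows = []
    for p in pops:
        row = {"component": p}
        for lo, hi, label in edges:
            mask = (truth[p] >= lo) & (truth[p] < hi)
            if lo == 0.0:
                mask &= truth[p] > 0  # unadmixed-in-this-component excluded
            row[label] = float((E.loc[mask, p] >= detect_at).mean()) if mask.any() else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("component")


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------


@dataclass
class EvannoTable:
    """Evanno statistics per K: mean/sd L(K), L'(K), |L''(K)|, delta K."""

    table: pd.DataFrame
    best_k: int | None


def evanno_delta_k(runs: dict) -> EvannoTable:
    """Evanno second-difference statistic over replicate log-probabilities.

    ``runs`` maps each K to a sequence of replicate log-probabilities
    L(K).  Requires at least three consecutive K values with >= 2
    replicates each.  delta K = mean|L''(K)| / sd L(K) is defined only for
    interior K with sd > 0; sd = 0 leaves delta K NaN there (flagged).
    Invariant to adding a constant to all log-probabilities.
    """
    ks = sorted(runs)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >=3 consecutive K values")
    if any(len(runs[k]) < 2 for k in ks):
        raise ValueError("need >=2 replicates per K")
    mean = {k: float(np.mean(runs[k])) for k in ks}
    sd = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean.get(k + 1, np.nan) - mean[k] if k + 1 in mean else np.nan
        if k - 1 in mean and k + 1 in mean:
            lpp = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            dk = lpp / sd[k] if sd[k] > 0 else float("nan")
        else:
            lpp, dk = np.nan, np.nan
        rows.append(
            {"K": k, "mean_LK": mean[k], "sd_LK": sd[k], "Lp": lp, "abs_Lpp": lpp, "delta_K": dk}
        )
    table = pd.DataFrame(rows).set_index("K")
    dk = table["delta_K"].dropna()
    best = int(dk.idxmax()) if len(dk) else None
    return EvannoTable(table, best)


# ---------------------------------------------------------------------------
# Panel composition audit
# ---------------------------------------------------------------------------

PANEL_SOURCE_COLUMNS = ("kk_piap", "gaims", "lace", "other")


def load_bt_panel() -> pd.DataFrame:
    """The packaged transcription of the BT ancestry-panel composition table.

    One row per binary ancestry SNP (plus two appearance SNPs previously
    used as AIMs, marked ``appearance = 1``) with its target group and the
    established forensic panels it was sourced from.
    """
    with resources.files("aimkit.data").joinpath("bt_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    df["appearance"] = df["appearance"].astype(int)
    return df


def panel_audit(panel: pd.DataFrame, include_appearance: bool = False) -> dict:
    """Composition counts for a panel table.

    ``panel`` needs columns ``snp_id``, ``target_group`` and either a
    ``source_panels`` column (semicolon-separated) or the per-panel
    columns ``kk_piap``/``gaims``/``lace``/``other``; an optional
    ``is_triallelic`` column separates binary from tri-allelic counts and
    an optional ``appearance`` column marks shared appearance SNPs
    (excluded from the counts by default).

    Returns per-target-group SNP counts, the number of SNPs drawn from
    two or more source panels, binary/tri-allelic totals and the overall
    AIM count.  Duplicate rsIDs raise ``ValueError``.
    """
    df = panel.copy()
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate rsID in panel: {dup}")
    if not include_appearance and "appearance" in df.columns:
        df = df[df["appearance"].astype(int) == 0]
    if "source_panels" in df.columns:
        n_sources = df["source_panels"].fillna("").map(lambda s: len([p for p in s.split(";") if p]))
    else:
        present = [c for c in PANEL_SOURCE_COLUMNS if c in df.columns]
        n_sources = (df[present].fillna("") != "").sum(axis=1)
    if "is_triallelic" in df.columns:
        tri = df["is_triallelic"].astype(bool)
    else:
        tri = pd.Series(False, index=df.index)
    return {
        "per_group": df.groupby("target_group")["snp_id"].count().to_dict(),
        "multi_panel": int((n_sources >= 2).sum()),
        "n_binary": int((~tri).sum()),
        "n_triallelic": int(tri.sum()),
        "n_total": int(len(df)),
    }


# ---------------------------------------------------------------------------
# Diplotype (2-SNP microhaplotype) encoding
# ---------------------------------------------------------------------------

_PSEUDO = ("A", "C", "G", "T")


def diplotype_alphabet(alleles1, alleles2) -> dict:
    """Mapping from 2-SNP haplotype combinations to pseudo-SNP alleles.

    All haplotype combinations (first SNP's allele followed by the
    second's) are sorted alphabetically and mapped onto A, C, G, T in
    order — e.g. for allele pairs (A,C) x (A,G): AA->A, AG->C, CA->G,
    CG->T.  More than four combinations (a tri-allelic member) extends
    the alphabet with a warning.
    """
    combos = sorted(a1 + a2 for a1 in alleles1 for a2 in alleles2)
    if len(combos) > 4:
        warnings.warn(
            f"{len(combos)} haplotype combinations exceed the 4-letter "
            "nucleotide alphabet; extending with numbered symbols",
            stacklevel=2,
        )
        symbols = list(_PSEUDO) + [f"X{i}" for i in range(1, len(combos) - 3)]
    else:
        symbols = list(_PSEUDO)
    return {c: symbols[i] for i, c in enumerate(combos)}


def diplotype_encode(haplotypes, alleles1, alleles2) -> str:
    """Recode an individual's phased 2-SNP diplotype as a pseudo-genotype.

    ``haplotypes`` is the pair of phased haplotypes, each a 2-character
    string (first SNP's allele then second's), e.g. ``("AA", "CG")``.
    Returns the unordered pseudo-genotype under
    :func:`diplotype_alphabet`, canonically sorted (e.g. ``"AT"``).
    """
    if len(haplotypes) != 2:
        raise ValueError("need exactly two phased haplotypes")
    mapping = diplotype_alphabet(alleles1, alleles2)
    coded = []
    for h in haplotypes:
        if h not in mapping:
            raise ValueError(f"haplotype {h!r} not in {sorted(mapping)} (unphased or bad input?)")
        coded.append(mapping[h])
    return "".join(sorted(coded))
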