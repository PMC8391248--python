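"""Synthetic population, panel and genotype generation.

Emulates the statistical structure the analysis stack assumes — six
continental-style reference groups typed at an ancestry-informative SNP
panel — so every stage (informativeness, classification, co-ancestry,
concordance) can be exercised end-to-end without external data.

Population allele frequencies follow the Balding-Nichols drift model:
each locus has an ancestral frequency vector, and each population draws
its own vector from a Dirichlet with that mean and concentration
(1 - F)/F, so F acts as an FST-like divergence parameter.  Loci assigned
to a target group additionally have that group's informative allele
boosted toward fixation until the locus's population-specific divergence
(PSD) clears a configurable floor, mimicking how real AIMs are
ascertained.  Genotypes are two independent allele draws per locus
(Hardy-Weinberg, no linkage); admixed individuals draw each allele
copy's population of origin from their co-ancestry simplex q.

The default configuration mirrors the BT ancestry panel's shape: 88
binary SNPs split 7/15/16/20/13/17 across AFR/EUR/EAS/SAS/OCE/AMR plus
15 tri-allelic SNPs, a 520-sample six-group reference set
(108/99/103/103/28/79), strong drift for the well-differentiated groups
and weak drift plus a low PSD floor for SAS, whose differentiation from
EUR/EAS is known to be much weaker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GROUPS, FrequencyTable, GenotypeMatrix, PanelSnp
from .informativeness import population_specific_divergence

__all__ = [
    "SyntheticConfig",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_admixed",
    "inject_errors",
    "build_reference_dataset",
    "DEFAULT_N_LOCI",
    "DEFAULT_N_SAMPLES",
    "DEFAULT_DIVERGENCE",
    "DEFAULT_PSD_FLOOR",
]

#: Binary loci per target group (the BT panel's per-group composition).
DEFAULT_N_LOCI = {"AFR": 7, "EUR": 15, "EAS": 16, "SAS": 20, "OCE": 13, "AMR": 17}

#: Reference samples per group (the 520-sample standardised reference set).
DEFAULT_N_SAMPLES = {"AFR": 108, "EUR": 99, "EAS": 103, "SAS": 103, "OCE": 28, "AMR": 79}

#: Balding-Nichols drift per group; SAS is deliberately weakly drifted.
DEFAULT_DIVERGENCE = {"AFR": 0.30, "EUR": 0.20, "EAS": 0.20, "SAS": 0.08, "OCE": 0.35, "AMR": 0.35}

#: Minimum PSD enforced for a group's own informative loci (nats).
DEFAULT_PSD_FLOOR = {"AFR": 0.40, "EUR": 0.40, "EAS": 0.40, "SAS": 0.12, "OCE": 0.40, "AMR": 0.40}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study design.

    ``admixture_design`` is a list of (q, n) pairs: ``q`` maps group ->
    co-ancestry proportion (a simplex over ``groups``), ``n`` the number
    of admixed individuals to simulate with that q.  ``seed`` is
    mandatory; all generators are bit-reproducible given it.
    """

    seed: int
    groups: tuple = GROUPS
    n_loci: Mapping = field(default_factory=lambda: dict(DEFAULT_N_LOCI))
    n_triallelic: int = 15
    divergence: Mapping = field(default_factory=lambda: dict(DEFAULT_DIVERGENCE))
    psd_floor: Mapping = field(default_factory=lambda: dict(DEFAULT_PSD_FLOOR))
    n_samples: Mapping = field(default_factory=lambda: dict(DEFAULT_N_SAMPLES))
    admixture_design: list = field(default_factory=list)
    error_rate: float = 0.0
    nocall_rate: float = 0.0
    max_attempts: int = 500

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for r in (self.error_rate, self.nocall_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        for g in self.groups:
            if not 0.0 < self.divergence[g] < 1.0:
                raise ValueError(f"divergence F for {g} must be in (0, 1)")
        for q, _ in self.admixture_design:
            tot = sum(q.get(g, 0.0) for g in self.groups)
            if abs(tot - 1.0) > 1e-6 or any(v < 0 for v in q.values()):
                raise ValueError(f"admixture design q {q} is not a simplex")


_EPS = 1e-4  # frequencies are kept off the simplex boundary


def _clip_simplex(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return p / p.sum()


def _bn_draw(rng, ancestral: np.ndarray, F: float) -> np.ndarray:
    """One population's frequency vector under Balding-Nichols drift."""
    conc = (1.0 - F) / F
    return _clip_simplex(rng.dirichlet(np.maximum(ancestral, _EPS) * conc))


def _boosted_locus(rng, groups, divergence, target, floor, n_alleles, max_attempts):
    """Draw per-population vectors for a target-group locus with PSD >= floor.

    The target group's informative allele is pushed toward fixation while
    the remaining groups drift around a low ancestral frequency; rejection
    sampling enforces the PSD floor.  Strong floors use a near-fixed
    proposal, weak floors a milder one, so accepted loci sit just above
    the floor rather than far beyond it.
    """
    t_lo = 0.85 if floor >= 0.3 else 0.45
    a_hi = 0.10 if floor >= 0.3 else 0.30
    for _ in range(max_attempts):
        p_target = rng.uniform(t_lo, 0.995)
        a_low = rng.uniform(0.01, a_hi)
        # ancestral vector for the non-informative alleles
        if n_alleles == 2:
            anc = np.array([a_low, 1.0 - a_low])
        else:
            rest = rng.dirichlet([2.0, 2.0]) * (1.0 - a_low)
            anc = np.concatenate([[a_low], rest])
        vectors = np.empty((len(groups), n_alleles))
        for k, g in enumerate(groups):
            if g == target:
                rest = anc[1:] / anc[1:].sum() * (1.0 - p_target)
                vectors[k] = _clip_simplex(np.concatenate([[p_target], rest]))
            else:
                vectors[k] = _bn_draw(rng, anc, divergence[g])
        if population_specific_divergence(vectors, list(groups), target) >= floor:
            return vectors
    raise RuntimeError(
        f"could not reach PSD floor {floor} for group {target} in "
        f"{max_attempts} attempts; lower the floor"
    )


def simulate_frequencies(cfg: SyntheticConfig) -> FrequencyTable:
    """Simulate a per-group allele-frequency table for the panel.

    Binary loci have ancestral frequency ~ Uniform(0.1, 0.9); tri-allelic
    loci draw their ancestral vector from a Dirichlet.  Every locus is
    assigned a target group and boosted to clear that group's PSD floor.
    All emitted frequencies are strictly inside (0, 1), so the table can
    be used directly for likelihood computations.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.groups)
    loci, freqs = [], []
    assignments = []  # (target group, n_alleles)
    for g in groups:
        assignments += [(g, 2)] * int(cfg.n_loci[g])
    for i in range(cfg.n_triallelic):
        assignments.append((groups[i % len(groups)], 3))
    for idx, (g, n_alleles) in enumerate(assignments):
        alleles = tuple(rng.permutation(["A", "C", "G", "T"])[:n_alleles])
        snp = PanelSnp(
            snp_id=f"rs9{idx:04d}",
            chromosome="1",
            position=1000 + idx,
            alleles=tuple(sorted(alleles)),
            target_group=g,
        )
        vectors = _boosted_locus(
            rng, groups, cfg.divergence, g, cfg.psd_floor[g], n_alleles, cfg.max_attempts
        )
        loci.append(snp)
        freqs.append(vectors)
    sizes = np.zeros((len(loci), len(groups)))
    return FrequencyTable(loci, groups, freqs, sizes)


def simulate_genotypes(
    freqs: FrequencyTable,
    n_per_group: Mapping,
    seed: int,
    training_flag: int = 1,
) -> GenotypeMatrix:
    """Draw reference genotypes under Hardy-Weinberg proportions.

    Each sample's genotype at each locus is two independent allele draws
    from its population's frequency vector.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    sample_ids, labels = [], []
    for g in freqs.populations:
        for i in range(int(n_per_group.get(g, 0))):
            sample_ids.append(f"{g}_{i + 1:04d}")
            labels.append(g)
    calls = np.empty((len(sample_ids), freqs.n_loci), dtype=object)
    for j, snp in enumerate(freqs.loci):
        for i, g in enumerate(labels):
            k = freqs.pop_index(g)
            pair = rng.choice(len(snp.alleles), size=2, p=freqs.freqs[j][k])
            calls[i, j] = "".join(sorted(snp.alleles[x] for x in pair))
    return GenotypeMatrix(sample_ids, labels, [training_flag] * len(sample_ids), freqs.loci, calls)


def simulate_admixed(
    freqs: FrequencyTable,
    design: Sequence,
    seed: int,
) -> tuple:
    """Draw admixed query individuals from a co-ancestry design.

    ``design`` is a list of (q, n) pairs where ``q`` maps population ->
    proportion.  Each allele copy independently draws its population of
    origin from q and then an allele from that population's vector.

    Returns ``(GenotypeMatrix, truth)`` where ``truth`` is a DataFrame
    with one column per population holding each sample's *realised*
    co-ancestry — the fraction of its allele copies actually drawn from
    that population — plus ``design_<pop>`` columns with the nominal q.
    The realised fractions are the correct comparator for proportion
    estimates: an individual simulated at q scatters binomially around it
    (sd ~ sqrt(q(1-q)/2L)), exactly as a real admixed genome's ancestry
    fraction differs from its population's typical admixture.  Training
    flags are all 0.
    """
    rng = np.random.default_rng(seed)
    pops = list(freqs.populations)
    sample_ids, q_rows = [], []
    for d, (q, n) in enumerate(design):
        qv = np.array([q.get(p, 0.0) for p in pops], dtype=float)
        if abs(qv.sum() - 1.0) > 1e-6 or (qv < 0).any():
            raise ValueError(f"design entry {d}: q is not a simplex over {pops}")
        for i in range(int(n)):
            sample_ids.append(f"adm{d}_{i + 1:04d}")
            q_rows.append(qv)
    calls = np.empty((len(sample_ids), freqs.n_loci), dtype=object)
    realised = np.zeros((len(sample_ids), len(pops)))
    for i, qv in enumerate(q_rows):
        for j, snp in enumerate(freqs.loci):
            pair = []
            for _ in range(2):
                k = rng.choice(len(pops), p=qv)
                realised[i, k] += 1
                pair.append(snp.alleles[rng.choice(len(snp.alleles), p=freqs.freqs[j][k])])
            calls[i, j] = "".join(sorted(pair))
    realised /= 2 * freqs.n_loci
    gm = GenotypeMatrix(sample_ids, [None] * len(sample_ids), [0] * len(sample_ids), freqs.loci, calls)
    truth = pd.DataFrame(realised, index=sample_ids, columns=pops)
    for k, p in enumerate(pops):
        truth[f"design_{p}"] = [qv[k] for qv in q_rows]
    return gm, truth


def _all_genotypes(alleles) -> list:
    return sorted(
        "".join(sorted((alleles[i], alleles[j])))
        for i in range(len(alleles))
        for j in range(i, len(alleles))
    )


def inject_errors(
    gm: GenotypeMatrix,
    error_rate: float = 0.0,
    nocall_rate: float = 0.0,
    seed: int = 0,
    n_errors: int | None = None,
    n_nocalls: int | None = None,
) -> tuple:
    """Perturb a call set with genotyping errors and no-calls.

    Rate mode (default): independently per cell, with ``nocall_rate`` the
    call is set MISSING; otherwise with ``error_rate`` it is replaced by
    a different random valid genotype at that locus.  Count mode
    (``n_errors``/``n_nocalls``): exactly that many distinct non-missing
    cells are changed, for building fixtures that match printed counts.

    Returns ``(perturbed copy, ledger)`` where the ledger is a DataFrame
    listing every changed cell (sample, locus, kind, before, after).
    Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    out = gm.copy()
    genos = [_all_genotypes(s.alleles) for s in gm.loci]
    ledger = []

    def flip(i, j):
        cur = out.calls[i, j]
        alts = [g for g in genos[j] if g != cur]
        new = alts[rng.integers(len(alts))]
        out.calls[i, j] = new
        ledger.append(
            {
                "sample": gm.sample_ids[i],
                "locus": gm.loci[j].snp_id,
                "kind": "error",
                "before": cur,
                "after": new,
            }
        )

    def drop(i, j):
        cur = out.calls[i, j]
        out.calls[i, j] = None
        ledger.append(
            {
                "sample": gm.sample_ids[i],
                "locus": gm.loci[j].snp_id,
                "kind": "nocall",
                "before": cur,
                "after": None,
            }
        )

    if n_errors is not None or n_nocalls is not None:
        callable_cells = [
            (i, j)
            for i in range(gm.n_samples)
            for j in range(gm.n_loci)
            if gm.calls[i, j] is not None
        ]
        need = (n_errors or 0) + (n_nocalls or 0)
        if need > len(callable_cells):
            raise ValueError(f"cannot change {need} cells; only {len(callable_cells)} called")
        pick = rng.choice(len(callable_cells), size=need, replace=False)
        for x in pick[: (n_errors or 0)]:
            flip(*callable_cells[x])
        for x in pick[(n_errors or 0) :]:
            drop(*callable_cells[x])
    else:
        for i in range(gm.n_samples):
            for j in range(gm.n_loci):
                if out.calls[i, j] is None:
                    continue
                u = rng.random()
                if u < nocall_rate:
                    drop(i, j)
                elif u < nocall_rate + error_rate:
                    flip(i, j)
    cols = ["sample", "locus", "kind", "before", "after"]
    return out, pd.DataFrame(ledger, columns=cols)


def build_reference_dataset(cfg: SyntheticConfig) -> tuple:
    """Convenience end-to-end builder: (true frequencies, reference matrix).

    Draws the panel's per-group frequency table and a labelled reference
    genotype matrix (training flags 1) from one config; the genotype seed
    is derived from ``cfg.seed`` so the pair is jointly reproducible.
    """
    freqs = simulate_frequencies(cfg)
    gm = simulate_genotypes(freqs, cfg.n_samples, seed=(cfg.seed + 1) % (2**31))
    return freqs, gm
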