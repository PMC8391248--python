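"""End-to-end study workflows over the synthetic six-group design.

These functions wire the generator to the analysis modules under the
package's standard study conditions: a 520-sample six-group reference
panel of ~103 ancestry-informative SNPs, two-way admixture cohorts, and
concordance fixtures built from exact injected-change counts.  They are
used by the acceptance script and the higher-level tests, and are the
quickest way to reproduce the headline numbers from Python.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bayes_classifier import loo_crossval
from .coancestry import gda_coancestry, supervised_admixture
from .concordance import compare_callsets, round_half_up
from .core_io import GROUPS, FrequencyTable, GenotypeMatrix, PanelSnp
from .informativeness import cumulative_psd
from .synthetic_data import (
    SyntheticConfig,
    build_reference_dataset,
    inject_errors,
    simulate_admixed,
)

__all__ = [
    "restrict_populations",
    "crossval_study",
    "mixture_recovery_study",
    "gda_vs_em_study",
    "concordance_fixture_study",
]

#: The K:4 reference subset used for admixture estimation in the
#: two-way-cohort studies (major continental groups only, keeping the
#: inferred clusters simple).
K4_GROUPS = ("AFR", "EUR", "AMR", "EAS")


def restrict_populations(ft: FrequencyTable, populations) -> FrequencyTable:
    """A frequency table restricted to a subset of its populations."""
    idx = [ft.populations.index(p) for p in populations]
    return FrequencyTable(
        ft.loci, list(populations), [f[idx, :] for f in ft.freqs], ft.sample_sizes[:, idx]
    )


def crossval_study(seed: int) -> dict:
    """Reference-panel leave-one-out cross-validation under default conditions.

    Builds the 520-sample six-group reference set, runs one-out
    cross-validation (pseudo-count smoothing 1) and summarises accuracy,
    likelihood-ratio strength and the panel's cumulative PSD balance.
    """
    cfg = SyntheticConfig(seed=seed)
    freqs, gm = build_reference_dataset(cfg)
    rep = loo_crossval(gm, smoothing=1.0)
    lrs = np.array([r.lr_best_vs_second for r in rep.results])
    assign = {s.snp_id: s.target_group for s in freqs.loci}
    return {
        "config": cfg,
        "frequencies": freqs,
        "matrix": gm,
        "report": rep,
        "overall_pct": rep.overall_pct,
        "median_lr": float(np.median(lrs)),
        "pct_lr_above_1e9": 100.0 * float((lrs > 1e9).mean()),
        "cumulative_psd": cumulative_psd(freqs, assign, assigned_only=False),
    }


def mixture_recovery_study(seed: int, n_individuals: int = 200) -> dict:
    """Two-way AFR/EUR admixture recovery with minor components of 10-30%.

    Individuals are simulated in equal blocks at minor EUR proportions
    0.10/0.15/0.20/0.30 and their co-ancestry estimated by supervised EM
    against the K:4 reference subset.  Detection means an estimated minor
    component of at least 5% among individuals whose realised minor
    ancestry is at least 10%; the error metric is the mean absolute
    difference between estimated and realised minor proportions.
    """
    cfg = SyntheticConfig(seed=seed)
    freqs = build_reference_dataset(cfg)[0]
    f4 = restrict_populations(freqs, K4_GROUPS)
    block = n_individuals // 4
    design = [({"AFR": 1 - m, "EUR": m}, block) for m in (0.10, 0.15, 0.20, 0.30)]
    gm, truth = simulate_admixed(freqs, design, seed=(seed + 1) % (2**31))
    k = f4.populations.index("EUR")
    q_hat = np.array(
        [
            supervised_admixture(gm.sample_ids[i], gm.calls[i, :], f4).q[k]
            for i in range(gm.n_samples)
        ]
    )
    realised = truth["EUR"].to_numpy()
    sel = realised >= 0.10
    return {
        "q_hat": q_hat,
        "realised": realised,
        "detection_pct": 100.0 * float((q_hat[sel] >= 0.05).mean()),
        "mean_abs_error": float(np.abs(q_hat - realised).mean()),
        "n": int(gm.n_samples),
    }


def gda_vs_em_study(seed: int, n_individuals: int = 120) -> dict:
    """ACB-like cohort: distance-screen (GDA) vs EM minor-EUR estimates.

    Simulates African-Caribbean-style two-way admixture (minor EUR spread
    over 5-30%, cohort-mean AFR ~ 0.85).  EM runs against the K:4
    reference subset; the GDA screen runs against the full six-group
    reference, as a first-pass screen would.  Reports the fraction of
    individuals whose GDA minor-EUR estimate falls below the EM estimate.
    """
    cfg = SyntheticConfig(seed=seed)
    freqs = build_reference_dataset(cfg)[0]
    f4 = restrict_populations(freqs, K4_GROUPS)
    levels = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
    block = n_individuals // len(levels)
    design = [({"AFR": 1 - m, "EUR": m}, block) for m in levels]
    gm, _ = simulate_admixed(freqs, design, seed=(seed + 2) % (2**31))
    k4 = f4.populations.index("EUR")
    k6 = freqs.populations.index("EUR")
    em_q, gda_q = [], []
    for i in range(gm.n_samples):
        em_q.append(supervised_admixture(gm.sample_ids[i], gm.calls[i, :], f4).q[k4])
        gda_q.append(gda_coancestry(gm.sample_ids[i], gm.calls[i, :], freqs).q[k6])
    em_q, gda_q = np.array(em_q), np.array(gda_q)
    return {
        "em_minor": em_q,
        "gda_minor": gda_q,
        "pct_gda_below_em": 100.0 * float((gda_q < em_q).mean()),
        "n": int(gm.n_samples),
    }


def _constant_matrix(n_samples: int, n_loci: int) -> GenotypeMatrix:
    loci = [
        PanelSnp(snp_id=f"rs{j:05d}", chromosome="1", position=j + 1, alleles=("A", "G"))
        for j in range(n_loci)
    ]
    calls = np.full((n_samples, n_loci), "AA", dtype=object)
    return GenotypeMatrix(
        [f"s{i:04d}" for i in range(n_samples)],
        [None] * n_samples,
        [0] * n_samples,
        loci,
        calls,
    )


def concordance_fixture_study(seed: int) -> dict:
    """Concordance audits on fixtures with exact injected-change counts.

    Three comparisons mirroring a developmental-assay audit:

    * a 151-locus x 272-sample grid with exactly 17 discordances;
    * a single locus typed in 277 samples with 15 discordances, and one
      with 29 discordances (a rare-allele dropout pattern);
    * no-call injection at exact counts giving per-callset no-call rates
      of 0.2% and 0.6%.
    """
    a = _constant_matrix(272, 151)
    b, _ = inject_errors(a, seed=seed, n_errors=17)
    grid = compare_callsets(a, b)

    a1 = _constant_matrix(277, 1)
    b1, _ = inject_errors(a1, seed=seed + 1, n_errors=15)
    locus15 = compare_callsets(a1, b1)
    b2, _ = inject_errors(a1, seed=seed + 2, n_errors=29)
    locus29 = compare_callsets(a1, b2)

    n_cells = 272 * 151
    wgs, _ = inject_errors(a, seed=seed + 3, n_nocalls=round(0.002 * n_cells))
    mps, _ = inject_errors(a, seed=seed + 4, n_nocalls=round(0.006 * n_cells))
    nocall = compare_callsets(mps, wgs)

    def locus_pct(rep, ndigits):
        row = rep.per_locus.iloc[0]
        return round_half_up(100.0 * row["n_discordant"] / row["n_compared"], ndigits)

    return {
        "grid_concordance_pct": round_half_up(grid.concordance_pct, 2),
        "grid_discordances": grid.total_discordant,
        "locus_discordancy_pct_15": locus_pct(locus15, 1),
        "locus_discordancy_pct_29": locus_pct(locus29, 2),
        "nocall_pct_mps": round_half_up(nocall.nocall_pct_a, 1),
        "nocall_pct_wgs": round_half_up(nocall.nocall_pct_b, 1),
        "reports": {"grid": grid, "locus15": locus15, "locus29": locus29},
    }
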