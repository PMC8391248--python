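"""Pairwise genotype-callset concordance auditing.

Given two genotype matrices for overlapping samples and loci (e.g. an
MPS assay's calls vs. a whole-genome-sequencing database's calls for the
same DNAs), counts per-locus and overall discordant genotypes and
no-calls, and flags outlier loci with elevated discordance.

A cell enters the comparison only when it is non-missing in both call
sets; genotypes are compared as unordered allele multisets (phase is
ignored).  Half-calls are treated as no-calls upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix

__all__ = ["ConcordanceReport", "compare_callsets", "flag_outlier_loci"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConcordanceReport:
    """Outcome of a pairwise callset comparison.

    ``per_locus`` has one row per shared locus with columns
    ``n_compared``, ``n_discordant``, ``n_nocall_a``, ``n_nocall_b``.
    Percentages are carried at full precision; use
    :func:`round_half_up` (2 decimals) for display.
    """

    per_locus: pd.DataFrame
    per_sample: pd.Series
    shared_samples: list
    shared_loci: list
    only_in_a: dict  # {"samples": [...], "loci": [...]}
    only_in_b: dict
    total_compared: int
    total_discordant: int
    concordance_pct: float
    nocall_pct_a: float
    nocall_pct_b: float


def compare_callsets(a: GenotypeMatrix, b: GenotypeMatrix) -> ConcordanceReport:
    """Compare two genotype call sets over their shared samples and loci.

    Samples and loci are matched by id; entries present in only one call
    set are excluded from the comparison and listed in the report.
    Raises ``ValueError`` when the sample or locus intersection is empty.
    """
    a_samples = {s: i for i, s in enumerate(a.sample_ids)}
    b_samples = {s: i for i, s in enumerate(b.sample_ids)}
    a_loci = {s.snp_id: j for j, s in enumerate(a.loci)}
    b_loci = {s.snp_id: j for j, s in enumerate(b.loci)}
    samples = [s for s in a.sample_ids if s in b_samples]
    loci = [s.snp_id for s in a.loci if s.snp_id in b_loci]
    if not samples:
        raise ValueError("no shared samples between the call sets")
    if not loci:
        raise ValueError("no shared loci between the call sets")

    rows = []
    per_sample = {s: 0 for s in samples}
    for lid in loci:
        ja, jb = a_loci[lid], b_loci[lid]
        n_cmp = n_dis = na = nb = 0
        for s in samples:
            ca = a.calls[a_samples[s], ja]
            cb = b.calls[b_samples[s], jb]
            if ca is None:
                na += 1
            if cb is None:
                nb += 1
            if ca is None or cb is None:
                continue
            n_cmp += 1
            if ca != cb:
                n_dis += 1
                per_sample[s] += 1
        rows.append(
            {
                "locus": lid,
                "n_compared": n_cmp,
                "n_discordant": n_dis,
                "n_nocall_a": na,
                "n_nocall_b": nb,
            }
        )
    per_locus = pd.DataFrame(rows).set_index("locus")
    total_cmp = int(per_locus["n_compared"].sum())
    total_dis = int(per_locus["n_discordant"].sum())
    n_cells = len(samples) * len(loci)
    return ConcordanceReport(
        per_locus=per_locus,
        per_sample=pd.Series(per_sample, name="n_discordant"),
        shared_samples=samples,
        shared_loci=loci,
        only_in_a={
            "samples": [s for s in a.sample_ids if s not in b_samples],
            "loci": [s.snp_id for s in a.loci if s.snp_id not in b_loci],
        },
        only_in_b={
            "samples": [s for s in b.sample_ids if s not in a_samples],
            "loci": [s.snp_id for s in b.loci if s.snp_id not in a_loci],
        },
        total_compared=total_cmp,
        total_discordant=total_dis,
        concordance_pct=100.0 * (1.0 - total_dis / total_cmp) if total_cmp else float("nan"),
        nocall_pct_a=100.0 * per_locus["n_nocall_a"].sum() / n_cells,
        nocall_pct_b=100.0 * per_locus["n_nocall_b"].sum() / n_cells,
    )


def flag_outlier_loci(report: ConcordanceReport, threshold: int) -> pd.DataFrame:
    """Loci with at least ``threshold`` discordances, worst first.

    Sorted by descending discordance count, ties broken by ascending
    rsID.  Returns the corresponding rows of the per-locus table.
    """
    sub = report.per_locus[report.per_locus["n_discordant"] >= threshold]
    order = sorted(sub.index, key=lambda s: (-sub.loc[s, "n_discordant"], s))
    return sub.loc[order]
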