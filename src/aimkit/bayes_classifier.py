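"""Snipper-style naive-Bayes ancestry classification.

Each reference population is summarised by smoothed allele frequencies;
a query profile's likelihood under a population is the product over
non-missing loci of Hardy-Weinberg genotype probabilities (p_a^2 for a
homozygote, 2 p_a p_b for a heterozygote).  The classification strength
is the Bayes likelihood ratio between the best and second-best
population, reported numerically and as a verbose statement ("more than
1 billion times more likely ...").

Leave-one-out cross-validation re-estimates every population's allele
frequencies with the held-out sample removed before classifying it, and
assembles a confusion matrix with per-group and overall
correct-classification percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    FrequencyTable,
    GenotypeMatrix,
    allele_counts,
    frequencies_from_counts,
)

__all__ = [
    "genotype_log_likelihood",
    "classify",
    "loo_crossval",
    "ClassificationResult",
    "CrossValidationReport",
]


def genotype_log_likelihood(call: str, alleles, freq_vector) -> float:
    """Log Hardy-Weinberg probability of an unordered genotype call.

    homozygote aa -> 2 ln p_a; heterozygote ab -> ln 2 + ln p_a + ln p_b.
    Frequencies must be strictly positive for the called alleles (use a
    smoothed frequency table).
    """
    alleles = list(alleles)
    f = np.asarray(freq_vector, dtype=float)
    a, b = call[0], call[1]
    pa = f[alleles.index(a)]
    pb = f[alleles.index(b)]
    if pa <= 0 or pb <= 0:
        raise ValueError(
            f"zero frequency for called allele in {call!r}; "
            "estimate frequencies with smoothing > 0"
        )
    if a == b:
        return 2.0 * math.log(pa)
    return math.log(2.0) + math.log(pa) + math.log(pb)


def _verbose(lr: float, best: str, second: str) -> str:
    if lr == 1.0:
        return (
            f"The profile is equally likely to be from {best} and {second} (likelihood ratio 1)."
        )
    if lr >= 1e9:
        qual = "more than 1 billion times"
    elif lr >= 1e6:
        qual = "more than 1 million times"
    elif lr >= 1e3:
        qual = "more than 1,000 times"
    else:
        qual = f"{float(f'{lr:.3g}'):g} times"
    return (
        f"The profile is {qual} more likely to be from {best} "
        f"than from {second}."
    )


@dataclass
class ClassificationResult:
    """Per-sample classification outcome."""

    sample_id: str
    log_likelihoods: dict  # population -> log-likelihood (nats, incl. prior)
    loci_used: int
    ranked: list  # populations, best first
    lr_best_vs_second: float
    verbose_statement: str

    @property
    def best(self) -> str:
        return self.ranked[0]

    @property
    def is_tie(self) -> bool:
        return self.lr_best_vs_second == 1.0


def classify(
    sample_id: str,
    calls,
    freqs: FrequencyTable,
    priors: dict | None = None,
) -> ClassificationResult:
    """Classify one profile against the populations of a frequency table.

    ``calls`` is a sequence aligned with ``freqs.loci`` of canonical
    genotype strings or ``None``; missing loci are skipped (the likelihood
    is a product over observed loci only) and counted in ``loci_used``.
    ``priors`` default to uniform.  Requires at least one non-missing
    locus.  An exact tie between the top two populations is reported with
    likelihood ratio 1.
    """
    pops = freqs.populations
    if priors is None:
        log_prior = {p: 0.0 for p in pops}  # uniform prior cancels in ratios
    else:
        tot = sum(priors[p] for p in pops)
        log_prior = {p: math.log(priors[p] / tot) for p in pops}
    loglik = {p: log_prior[p] for p in pops}
    used = 0
    for j, snp in enumerate(freqs.loci):
        c = calls[j]
        if c is None:
            continue
        used += 1
        for k, p in enumerate(pops):
            loglik[p] += genotype_log_likelihood(c, snp.alleles, freqs.freqs[j][k])
    if used == 0:
        raise ValueError(f"sample {sample_id}: all loci missing, cannot classify")
    ranked = sorted(pops, key=lambda p: (-loglik[p], p))
    delta = loglik[ranked[0]] - loglik[ranked[1]]
    lr = math.exp(min(delta, 700.0)) if delta < 700.0 else math.inf
    lr = max(lr, 1.0)
    return ClassificationResult(
        sample_id=sample_id,
        log_likelihoods=loglik,
        loci_used=used,
        ranked=ranked,
        lr_best_vs_second=lr,
        verbose_statement=_verbose(lr, ranked[0], ranked[1]),
    )


@dataclass
class CrossValidationReport:
    """Confusion matrix and success percentages from one-out cross-validation."""

    confusion: pd.DataFrame  # rows true group, columns assigned group
    per_group_pct: dict
    overall_pct: float
    results: list = field(default_factory=list)
    unclassifiable: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return int(self.confusion.values.sum())


def loo_crossval(gm: GenotypeMatrix, smoothing: float = 1.0) -> CrossValidationReport:
    """One-out cross-validation of the labelled training samples.

    For each training sample the population allele counts are re-computed
    with that sample's alleles removed, frequencies re-estimated with the
    given pseudo-count smoothing, and the sample classified against them.
    A fold whose own group would drop to zero usable chromosomes is still
    classifiable whenever smoothing > 0; a fold that cannot be classified
    at all (all loci missing) is reported as unclassifiable.
    """
    pops, base_counts = allele_counts(gm)
    if len(pops) < 2:
        raise ValueError("need at least two labelled groups for cross-validation")
    pop_idx = {p: k for k, p in enumerate(pops)}
    aidx = [{a: x for x, a in enumerate(s.alleles)} for s in gm.loci]

    confusion = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    results, unclassifiable = [], []
    for i in range(gm.n_samples):
        if gm.training_flags[i] != 1:
            continue
        true_pop = gm.population_labels[i]
        k = pop_idx[true_pop]
        counts = [c.copy() for c in base_counts]
        for j in range(gm.n_loci):
            c = gm.calls[i, j]
            if c is None:
                continue
            counts[j][k, aidx[j][c[0]]] -= 1
            counts[j][k, aidx[j][c[1]]] -= 1
        try:
            ft = frequencies_from_counts(gm.loci, pops, counts, smoothing)
            res = classify(gm.sample_ids[i], gm.calls[i, :], ft)
        except ValueError as e:
            unclassifiable.append((gm.sample_ids[i], str(e)))
            continue
        results.append((true_pop, res))
        confusion.loc[true_pop, res.best] += 1

    per_group = {}
    for p in pops:
        n = int(confusion.loc[p].sum())
        per_group[p] = 100.0 * confusion.loc[p, p] / n if n else float("nan")
    total = int(confusion.values.sum())
    overall = 100.0 * np.trace(confusion.values) / total if total else float("nan")
    return CrossValidationReport(
        confusion=confusion,
        per_group_pct=per_group,
        overall_pct=overall,
        results=[r for _, r in results],
        unclassifiable=unclassifiable,
    )
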