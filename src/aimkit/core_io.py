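"""Data model and readers/writers for SNP genotype profiles.

The central containers are :class:`PanelSnp` (marker metadata),
:class:`GenotypeMatrix` (samples x loci unordered genotype calls with
population labels and training flags), and :class:`FrequencyTable`
(per-locus, per-population allele-frequency vectors).

Serialisation formats:

* the "Snipper grid" — a worksheet-style CSV whose first row carries the
  (profiles, markers, populations) counts and whose rightmost column is the
  0/1 training flag (POPFLAG) distinguishing reference from query profiles;
* VCF 4.x (read-only, via cyvcf2);
* the two-row-per-individual STRUCTURE raw input format (write-only);
* frequency tables as long-format TSV.

Genotypes are unordered pairs of nucleotide symbols, canonicalised to an
alphabetically sorted two-character string ("AG", never "GA"); a missing
call is represented in memory as ``None`` and on disk as ``"NN"``.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GROUPS",
    "PanelSnp",
    "Panel",
    "GenotypeMatrix",
    "FrequencyTable",
    "SnipperGrid",
    "FormatError",
    "UndefinedFrequencyError",
    "canonical_call",
    "read_panel",
    "read_vcf",
    "read_snipper_grid",
    "write_snipper_grid",
    "write_structure_input",
    "estimate_frequencies",
    "read_frequency_table",
    "write_frequency_table",
]

#: Sentinel for a missing genotype call (serialised as "NN").
MISSING = None

#: Canonical continental-scale group labels used throughout the package.
GROUPS = ("AFR", "EUR", "EAS", "SAS", "OCE", "AMR")

#: Valid target-group assignments for a panel SNP.
TARGET_GROUPS = GROUPS + ("EURASIA", "NONE")

NUCLEOTIDES = ("A", "C", "G", "T")


class FormatError(ValueError):
    """A file does not conform to its declared format/header contract."""


class UndefinedFrequencyError(ValueError):
    """An unsmoothed allele frequency is requested from zero observations."""


def canonical_call(call: str | tuple[str, str] | None) -> str | None:
    """Canonicalise a genotype call to an alphabetically sorted string.

    Accepts ``None``, the string ``"NN"``, a two-character string, or a
    pair of allele symbols.  Returns ``None`` for missing.
    """
    if call is None:
        return None
    if isinstance(call, str):
        if call.upper() == "NN" or call == "":
            return None
        if len(call) != 2:
            raise ValueError(f"genotype string must have 2 characters, got {call!r}")
        a, b = call[0].upper(), call[1].upper()
    else:
        a, b = (str(call[0]).upper(), str(call[1]).upper())
    return "".join(sorted((a, b)))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelSnp:
    """Metadata for one panel marker.

    Parameters
    ----------
    snp_id : str
        rsID (or any unique label).
    chromosome : str
        Chromosome label; free-form.
    position : int
        1-based coordinate (VCF convention).
    alleles : tuple of str
        2 or 3 distinct nucleotide symbols; the declared allele set.
    target_group : str
        The population group the marker is informative for, one of
        ``AFR/EUR/EAS/SAS/OCE/AMR/EURASIA/NONE``.
    source_panels : frozenset of str
        Names of established AIM panels the SNP was drawn from.
    """

    snp_id: str
    chromosome: str = "."
    position: int = 0
    alleles: tuple[str, ...] = ("A", "C")
    target_group: str = "NONE"
    source_panels: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        alleles = tuple(str(a).upper() for a in self.alleles)
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "source_panels", frozenset(self.source_panels))
        if not 2 <= len(alleles) <= 3:
            raise ValueError(f"{self.snp_id}: need 2-3 alleles, got {alleles}")
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"{self.snp_id}: duplicate alleles {alleles}")
        for a in alleles:
            if a not in NUCLEOTIDES:
                raise ValueError(f"{self.snp_id}: invalid allele symbol {a!r}")
        if not self.target_group:
            raise ValueError(f"{self.snp_id}: empty target group (use NONE)")

    @property
    def is_triallelic(self) -> bool:
        return len(self.alleles) == 3


class Panel:
    """An ordered collection of :class:`PanelSnp` with id/position lookup."""

    def __init__(self, snps: Iterable[PanelSnp]):
        self.snps: list[PanelSnp] = list(snps)
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rsIDs in panel")
        self._by_id = {s.snp_id: i for i, s in enumerate(self.snps)}
        self._by_pos = {(s.chromosome, s.position): i for i, s in enumerate(self.snps)}

    def __len__(self):
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def __getitem__(self, i):
        return self.snps[i]

    def index_of(self, snp_id: str) -> int:
        return self._by_id[snp_id]

    def match(self, chromosome: str, position: int, snp_id: str | None = None) -> int | None:
        """Locate a panel locus by chromosome+position, falling back to rsID."""
        i = self._by_pos.get((str(chromosome), int(position)))
        if i is None and snp_id:
            i = self._by_id.get(snp_id)
        return i


def read_panel(path) -> Panel:
    """Read panel metadata from TSV.

    Expected columns: ``snp_id``, ``alleles`` (e.g. "A/G" or "AG"),
    ``target_group``; optional ``chromosome``, ``position``,
    ``source_panels`` (semicolon-separated).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    snps = []
    for _, row in df.iterrows():
        alleles = tuple(a for a in row["alleles"].replace("/", "") if a.strip())
        panels = frozenset(p for p in row.get("source_panels", "").split(";") if p)
        snps.append(
            PanelSnp(
                snp_id=row["snp_id"],
                chromosome=str(row.get("chromosome", ".") or "."),
                position=int(row.get("position", 0) or 0),
                alleles=alleles,
                target_group=row.get("target_group", "NONE") or "NONE",
                source_panels=panels,
            )
        )
    return Panel(snps)


@dataclass
class GenotypeMatrix:
    """Samples x loci unordered genotype calls.

    ``calls`` is an object ndarray of shape (n_samples, n_loci) holding
    canonical two-character genotype strings or ``None`` (missing).
    ``population_labels`` holds a group label per sample, or ``None`` for
    unknown (query) profiles.  ``training_flags`` is the POPFLAG column:
    1 = reference profile contributing to allele-frequency estimates,
    0 = query profile.
    """

    sample_ids: list
    population_labels: list
    training_flags: list
    loci: list
    calls: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.population_labels = [p if p else None for p in self.population_labels]
        self.training_flags = [int(f) for f in self.training_flags]
        self.loci = list(self.loci)
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not all(f in (0, 1) for f in self.training_flags):
            raise ValueError("training flags must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def validate_calls(self) -> None:
        """Check that every called allele is in its locus's declared set."""
        for j, snp in enumerate(self.loci):
            allowed = set(snp.alleles)
            for i in range(self.n_samples):
                c = self.calls[i, j]
                if c is not None and not set(c) <= allowed:
                    raise ValueError(
                        f"sample {self.sample_ids[i]} locus {snp.snp_id}: "
                        f"call {c!r} outside declared alleles {snp.alleles}"
                    )

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            [self.population_labels[i] for i in idx],
            [self.training_flags[i] for i in idx],
            self.loci,
            self.calls[list(idx), :].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.population_labels),
            list(self.training_flags),
            list(self.loci),
            self.calls.copy(),
        )


@dataclass
class FrequencyTable:
    """Per-locus, per-population allele-frequency vectors.

    ``freqs[j]`` is an (n_populations, n_alleles_j) array over
    ``loci[j].alleles``; rows are probability simplexes.
    ``sample_sizes[j, k]`` counts the chromosomes observed for locus j in
    population k.
    """

    loci: list
    populations: list
    freqs: list
    sample_sizes: np.ndarray

    def __post_init__(self):
        self.loci = list(self.loci)
        self.populations = list(self.populations)
        self.freqs = [np.asarray(f, dtype=float) for f in self.freqs]
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=float)
        self.validate()

    def validate(self) -> None:
        K = len(self.populations)
        if len(self.freqs) != len(self.loci):
            raise ValueError("freqs/loci length mismatch")
        for snp, f in zip(self.loci, self.freqs):
            if f.shape != (K, len(snp.alleles)):
                raise ValueError(f"{snp.snp_id}: frequency array shape {f.shape}")
            if (f < 0).any():
                raise ValueError(f"{snp.snp_id}: negative frequency")
            if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{snp.snp_id}: frequency vectors do not sum to 1")
        if self.sample_sizes.shape != (len(self.loci), K):
            raise ValueError("sample_sizes shape mismatch")
        if (self.sample_sizes < 0).any():
            raise ValueError("negative sample sizes")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def pop_index(self, population: str) -> int:
        return self.populations.index(population)

    def freq_of(self, locus_idx: int, population: str, allele: str) -> float:
        snp = self.loci[locus_idx]
        return float(self.freqs[locus_idx][self.pop_index(population), snp.alleles.index(allele)])


@dataclass
class SnipperGrid:
    """Parsed Snipper worksheet: header counts plus profile rows.

    ``header_counts`` mirrors the worksheet's cells A1/B1/C1 —
    (n_profiles, n_markers, n_populations).
    """

    header_counts: tuple
    marker_ids: list
    rows: list  # (sample_id, [genotype strings], population label, flag)

    def validate(self) -> None:
        n_prof, n_mark, n_pop = self.header_counts
        if len(self.rows) != n_prof:
            raise FormatError(
                f"header declares {n_prof} profiles but grid has {len(self.rows)} rows"
            )
        if len(self.marker_ids) != n_mark:
            raise FormatError(
                f"header declares {n_mark} markers but grid has {len(self.marker_ids)} columns"
            )
        pops = {r[2] for r in self.rows if r[3] == 1 and r[2]}
        if len(pops) != n_pop:
            raise FormatError(
                f"header declares {n_pop} populations but reference rows carry {len(pops)}"
            )
        for r in self.rows:
            if r[3] not in (0, 1):
                raise FormatError(f"training flag must be 0/1, got {r[3]!r}")


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def read_vcf(path, panel: Panel) -> GenotypeMatrix:
    """Read genotype calls for panel loci from a VCF file.

    Loci are matched by chromosome+position first, rsID second.  Panel loci
    absent from the VCF are MISSING for all samples.  A VCF allele outside a
    locus's declared set flags the locus with a warning and sets all its
    calls MISSING.  Half-calls (one missing allele) are treated as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls = np.full((len(samples), len(panel)), None, dtype=object)
    seen = set()
    for variant in vcf:
        j = panel.match(variant.CHROM, variant.POS, variant.ID)
        if j is None or j in seen:
            continue
        seen.add(j)
        snp = panel[j]
        site_alleles = [variant.REF] + list(variant.ALT)
        used = {site_alleles[idx] for g in variant.genotypes for idx in g[:2] if idx >= 0}
        if not used <= set(snp.alleles):
            warnings.warn(
                f"{snp.snp_id}: VCF alleles {sorted(used)} outside panel set "
                f"{snp.alleles}; calls set MISSING",
                stacklevel=2,
            )
            continue
        for i, g in enumerate(variant.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                continue
            calls[i, j] = canonical_call((site_alleles[a], site_alleles[b]))
    vcf.close()
    return GenotypeMatrix(samples, [None] * len(samples), [0] * len(samples), list(panel), calls)


# ---------------------------------------------------------------------------
# Snipper grid CSV
# ---------------------------------------------------------------------------


def write_snipper_grid(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a Snipper training-grid CSV.

    Layout: row 1 carries (n_profiles, n_markers, n_populations) in its
    first three cells; row 2 is the column header; each profile row ends
    with its population label and the 0/1 training flag in the rightmost
    column.  Populations are counted over flagged reference rows only.
    """
    n_pop = len({p for p, f in zip(gm.population_labels, gm.training_flags) if f == 1 and p})
    for i in range(gm.n_samples):
        if gm.n_loci and all(c is None for c in gm.calls[i, :]):
            warnings.warn(f"sample {gm.sample_ids[i]} has no calls at any locus", stacklevel=2)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([gm.n_samples, gm.n_loci, n_pop])
        w.writerow(["sample"] + [s.snp_id for s in gm.loci] + ["population", "flag"])
        for i in range(gm.n_samples):
            genos = [c if c is not None else "NN" for c in gm.calls[i, :]]
            pop = gm.population_labels[i] or ""
            w.writerow([gm.sample_ids[i]] + genos + [pop, gm.training_flags[i]])


def _grid_to_matrix(grid: SnipperGrid, panel: Panel | None) -> GenotypeMatrix:
    if panel is not None:
        loci = [panel[panel.index_of(m)] for m in grid.marker_ids]
    else:
        # Reconstruct minimal loci; alleles inferred from observed calls,
        # padded from A/C/G/T if fewer than two alleles were observed.
        loci = []
        for j, mid in enumerate(grid.marker_ids):
            observed = sorted({a for r in grid.rows if r[1][j] for a in (r[1][j] or "")})
            observed = [a for a in observed if a != "N"]
            for cand in NUCLEOTIDES:
                if len(observed) >= 2:
                    break
                if cand not in observed:
                    observed.append(cand)
            loci.append(PanelSnp(snp_id=mid, position=j + 1, alleles=tuple(sorted(observed))))
    calls = np.full((len(grid.rows), len(loci)), None, dtype=object)
    for i, (sid, genos, pop, flag) in enumerate(grid.rows):
        for j, g in enumerate(genos):
            calls[i, j] = canonical_call(g)
    return GenotypeMatrix(
        [r[0] for r in grid.rows],
        [r[2] or None for r in grid.rows],
        [r[3] for r in grid.rows],
        loci,
        calls,
    )


def read_snipper_grid(path, panel: Panel | None = None) -> GenotypeMatrix:
    """Read a Snipper grid CSV back into a GenotypeMatrix.

    Header counts are validated against the content; a mismatch raises
    :class:`FormatError` naming the inconsistent count.  Profiles flagged 0
    keep their population column but it is treated as unknown when empty.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if any(c.strip() for c in r)]
    if len(rows) < 2:
        raise FormatError("grid must have a count row and a header row")
    try:
        counts = tuple(int(x) for x in rows[0][:3])
    except ValueError as e:
        raise FormatError(f"unparseable header counts {rows[0][:3]}") from e
    header = rows[1]
    if header[0] != "sample" or header[-1] != "flag" or header[-2] != "population":
        raise FormatError("column header must be: sample, <markers...>, population, flag")
    marker_ids = header[1:-2]
    data = []
    for r in rows[2:]:
        if len(r) != len(header):
            raise FormatError(f"row for {r[0]!r} has {len(r)} cells, expected {len(header)}")
        try:
            flag = int(r[-1])
        except ValueError as e:
            raise FormatError(f"bad training flag {r[-1]!r}") from e
        data.append((r[0], r[1:-2], r[-2], flag))
    grid = SnipperGrid(counts, marker_ids, data)
    grid.validate()
    return _grid_to_matrix(grid, panel)


# ---------------------------------------------------------------------------
# STRUCTURE export
# ---------------------------------------------------------------------------


def write_structure_input(gm: GenotypeMatrix, path) -> None:
    """Write a two-row-per-individual STRUCTURE raw input file.

    Columns: sample id, integer population code (0 for unknown), POPFLAG,
    then one integer-recoded allele per locus; MISSING is -9.  The
    allele-to-integer legend (per locus) and the population code map are
    written to ``<path>.legend.json``.
    """
    pops = sorted({p for p in gm.population_labels if p})
    pop_code = {p: i + 1 for i, p in enumerate(pops)}
    allele_code = {s.snp_id: {a: i + 1 for i, a in enumerate(s.alleles)} for s in gm.loci}
    with open(path, "w") as fh:
        fh.write(" ".join(s.snp_id for s in gm.loci) + "\n")
        for i in range(gm.n_samples):
            sid = gm.sample_ids[i]
            pop = pop_code.get(gm.population_labels[i], 0)
            flag = gm.training_flags[i]
            for copy in (0, 1):
                alleles = []
                for j, snp in enumerate(gm.loci):
                    c = gm.calls[i, j]
                    alleles.append(-9 if c is None else allele_code[snp.snp_id][c[copy]])
                fh.write(" ".join([str(sid), str(pop), str(flag)] + [str(a) for a in alleles]) + "\n")
    legend = {"populations": pop_code, "alleles": allele_code, "missing": -9}
    with open(str(path) + ".legend.json", "w") as fh:
        json.dump(legend, fh, indent=1)


# ---------------------------------------------------------------------------
# Allele-frequency estimation
# ---------------------------------------------------------------------------


def allele_counts(gm: GenotypeMatrix, populations: Sequence[str] | None = None):
    """Per-locus, per-population allele counts over training samples.

    Returns ``(populations, counts)`` where ``counts[j]`` is an
    (n_populations, n_alleles_j) integer array of chromosome counts.
    """
    if populations is None:
        populations = sorted(
            {p for p, f in zip(gm.population_labels, gm.training_flags) if f == 1 and p}
        )
    pop_idx = {p: k for k, p in enumerate(populations)}
    counts = [np.zeros((len(populations), len(s.alleles)), dtype=np.int64) for s in gm.loci]
    aidx = [{a: x for x, a in enumerate(s.alleles)} for s in gm.loci]
    for i in range(gm.n_samples):
        if gm.training_flags[i] != 1:
            continue
        pop = gm.population_labels[i]
        if pop is None:
            raise ValueError(f"training sample {gm.sample_ids[i]} has no population label")
        if pop not in pop_idx:
            continue
        k = pop_idx[pop]
        for j in range(gm.n_loci):
            c = gm.calls[i, j]
            if c is None:
                continue
            counts[j][k, aidx[j][c[0]]] += 1
            counts[j][k, aidx[j][c[1]]] += 1
    return list(populations), counts


def frequencies_from_counts(loci, populations, counts, smoothing: float = 0.0) -> FrequencyTable:
    """Turn allele counts into a FrequencyTable with pseudo-count smoothing.

    freq(a) = (count(a) + s) / (2N_called + s*A), A = number of declared
    alleles.  s = 0 is the plain maximum-likelihood estimate; any s > 0
    guarantees no frequency is exactly 0 or 1.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    freqs, sizes = [], np.zeros((len(loci), len(populations)))
    for j, snp in enumerate(loci):
        cnt = np.asarray(counts[j], dtype=float)
        tot = cnt.sum(axis=1)
        sizes[j, :] = tot
        if smoothing == 0.0 and (tot == 0).any():
            k = int(np.argmax(tot == 0))
            raise UndefinedFrequencyError(
                f"locus {snp.snp_id}, population {populations[k]}: zero called "
                f"chromosomes with smoothing 0; use smoothing > 0"
            )
        denom = tot + smoothing * len(snp.alleles)
        freqs.append((cnt + smoothing) / denom[:, None])
    return FrequencyTable(loci, list(populations), freqs, sizes)


def estimate_frequencies(
    gm: GenotypeMatrix,
    smoothing: float = 0.0,
    populations: Sequence[str] | None = None,
) -> FrequencyTable:
    """Estimate per-population allele frequencies from training samples.

    Missing calls are excluded from the chromosome counts.  With
    ``smoothing=0`` a population with zero called chromosomes at a locus
    raises :class:`UndefinedFrequencyError`.
    """
    pops, counts = allele_counts(gm, populations)
    if not pops:
        raise ValueError("no labelled training samples to estimate from")
    return frequencies_from_counts(gm.loci, pops, counts, smoothing)


def write_frequency_table(ft: FrequencyTable, path) -> None:
    """Write a FrequencyTable as long-format TSV (locus, population, allele, frequency, n_chrom)."""
    recs = []
    for j, snp in enumerate(ft.loci):
        for k, pop in enumerate(ft.populations):
            for x, a in enumerate(snp.alleles):
                recs.append(
                    {
                        "locus": snp.snp_id,
                        "population": pop,
                        "allele": a,
                        "frequency": ft.freqs[j][k, x],
                        "n_chrom": ft.sample_sizes[j, k],
                    }
                )
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def read_frequency_table(path, panel: Panel | None = None) -> FrequencyTable:
    """Read a long-format frequency TSV back into a FrequencyTable."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "population": str, "allele": str})
    loci_order = list(dict.fromkeys(df["locus"]))
    pops = list(dict.fromkeys(df["population"]))
    loci, freqs = [], []
    sizes = np.zeros((len(loci_order), len(pops)))
    for j, lid in enumerate(loci_order):
        sub = df[df["locus"] == lid]
        alleles = tuple(dict.fromkeys(sub["allele"]))
        if panel is not None:
            snp = panel[panel.index_of(lid)]
        else:
            snp = PanelSnp(snp_id=lid, position=j + 1, alleles=alleles)
        f = np.zeros((len(pops), len(snp.alleles)))
        for _, row in sub.iterrows():
            k = pops.index(row["population"])
            f[k, snp.alleles.index(row["allele"])] = row["frequency"]
            sizes[j, k] = row["n_chrom"]
        loci.append(snp)
        freqs.append(f)
    return FrequencyTable(loci, pops, freqs, sizes)
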