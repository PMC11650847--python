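"""SNP genotype containers, readers/writers, QC filters, and allele frequencies.

Dosages are additive counts of the counted allele (ALT for VCF input, the
file-declared allele for dosage TSVs), coded 0/1/2 with NaN for missing.
QC mirrors standard chip-data practice: drop animals with excess missingness,
exact-duplicate genotypes, or pedigree-genotype (opposing-homozygote)
conflicts; then drop markers with excess missingness or that are monomorphic.
Residual missingness is filled by per-marker mean imputation.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree

logger = logging.getLogger(__name__)


def _chrom_key(c: str):
    return (0, int(c)) if re.fullmatch(r"\d+", str(c)) else (1, str(c))


@dataclass
class GenotypeMatrix:
    """Animals x markers additive dosage matrix with a marker map."""

    animal_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray  # str labels, len = n_markers
    pos: np.ndarray  # 1-based bp, len = n_markers
    dosages: np.ndarray  # float (n_animals, n_markers), NaN = missing

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.animal_ids) or m != len(self.marker_ids) or m != len(self.pos):
            raise ValueError("inconsistent GenotypeMatrix dimensions")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0)) | (
            (self.dosages >= 0) & (self.dosages <= 2)
        )
        if not ok.all():
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def animal_index(self, ids: list[str]) -> np.ndarray:
        loc = {a: k for k, a in enumerate(self.animal_ids)}
        try:
            return np.array([loc[i] for i in ids], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"animal id not in genotype matrix: {e.args[0]!r}") from None

    def subset(self, animals: list[str] | None = None, markers: list[str] | None = None) -> "GenotypeMatrix":
        ai = self.animal_index(animals) if animals is not None else np.arange(self.n_animals)
        if markers is not None:
            mloc = {m: k for k, m in enumerate(self.marker_ids)}
            mi = np.array([mloc[m] for m in markers], dtype=np.int64)
        else:
            mi = np.arange(self.n_markers)
        return GenotypeMatrix(
            [self.animal_ids[k] for k in ai],
            [self.marker_ids[k] for k in mi],
            self.chrom[mi],
            self.pos[mi],
            self.dosages[np.ix_(ai, mi)],
        )

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = sorted(range(self.n_markers), key=lambda k: (_chrom_key(self.chrom[k]), self.pos[k]))
        return self.subset(markers=[self.marker_ids[k] for k in order])

    def allele_frequencies(self, animals: list[str] | None = None) -> np.ndarray:
        """Counted-allele frequency per marker over non-missing dosages."""
        d = self.dosages if animals is None else self.dosages[self.animal_index(animals)]
        with np.errstate(invalid="ignore"):
            return np.nansum(d, axis=0) / (2.0 * np.sum(~np.isnan(d), axis=0))

    def missing_fraction_animals(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_animals)
        return np.isnan(self.dosages).mean(axis=1)

    def missing_fraction_markers(self) -> np.ndarray:
        if self.n_animals == 0:
            return np.zeros(self.n_markers)
        return np.isnan(self.dosages).mean(axis=0)


# ---------------------------------------------------------------------------
# Readers / writers


class GenotypeFormatError(ValueError):
    pass


def read_vcf(path) -> tuple[GenotypeMatrix, int]:
    """Read biallelic SNPs from a VCF; returns (matrix, n_multiallelic_skipped).

    Dosage counts ALT-allele copies; ./. becomes missing. Multiallelic records
    are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animals = list(vcf.samples)
    marker_ids, chroms, poss, rows = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        rows.append(dos)
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNP VCF records", n_skipped)
    dosages = np.array(rows).T if rows else np.empty((len(animals), 0))
    g = GenotypeMatrix(animals, marker_ids, np.array(chroms, dtype=object), np.array(poss), dosages)
    return g.sorted_by_position(), n_skipped


def read_dosage_tsv(path, marker_map=None) -> GenotypeMatrix:
    """Dosage TSV: header of marker ids, first column animal id, cells 0/1/2/NA.

    ``marker_map`` is an optional TSV with columns marker, chrom, pos; without
    it, chromosome defaults to "0" and positions to the column order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    animal_col = df.columns[0]
    marker_ids = list(df.columns[1:])
    vals = df[marker_ids].replace({"NA": np.nan, "": np.nan}).to_numpy(dtype=float)
    if marker_map is not None:
        mm = pd.read_csv(marker_map, sep="\t", dtype={"marker": str, "chrom": str, "pos": np.int64})
        mm = mm.set_index("marker")
        missing = [m for m in marker_ids if m not in mm.index]
        if missing:
            raise GenotypeFormatError(f"markers absent from marker map: {missing[:5]}")
        chrom = mm.loc[marker_ids, "chrom"].to_numpy(dtype=object)
        pos = mm.loc[marker_ids, "pos"].to_numpy()
    else:
        chrom = np.array(["0"] * len(marker_ids), dtype=object)
        pos = np.arange(1, len(marker_ids) + 1)
    g = GenotypeMatrix(list(df[animal_col].astype(str)), marker_ids, chrom, pos, vals)
    return g.sorted_by_position()


def write_dosage_tsv(g: GenotypeMatrix, path, marker_map_path=None) -> None:
    df = pd.DataFrame(g.dosages, columns=g.marker_ids)
    # integers render without decimal point so the roundtrip is lossless
    df = df.map(lambda v: "NA" if np.isnan(v) else (str(int(v)) if float(v).is_integer() else repr(v)))
    df.insert(0, "animal_id", g.animal_ids)
    df.to_csv(path, sep="\t", index=False)
    if marker_map_path is not None:
        pd.DataFrame({"marker": g.marker_ids, "chrom": g.chrom, "pos": g.pos}).to_csv(
            marker_map_path, sep="\t", index=False
        )


def read_genotypes(path, fmt: str = "auto", marker_map=None) -> GenotypeMatrix:
    """Dispatch reader: fmt in {vcf, dosage-tsv, auto}."""
    p = str(path)
    if fmt == "auto":
        fmt = "vcf" if p.endswith((".vcf", ".vcf.gz")) else "dosage-tsv"
    if fmt == "vcf":
        return read_vcf(path)[0]
    if fmt == "dosage-tsv":
        return read_dosage_tsv(path, marker_map=marker_map)
    raise GenotypeFormatError(f"unknown genotype format {fmt!r}")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV: animal id column plus trait and factor columns."""
    df = pd.read_csv(path, sep="\t")
    df[df.columns[0]] = df[df.columns[0]].astype(str)
    return df


# ---------------------------------------------------------------------------
# QC


@dataclass
class QcReport:
    animals_removed: list[tuple[str, str]] = field(default_factory=list)
    markers_removed: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def counts(self) -> dict:
        out: dict[str, int] = {}
        for _, reason in self.animals_removed:
            out[f"animals_{reason}"] = out.get(f"animals_{reason}", 0) + 1
        for _, reason in self.markers_removed:
            out[f"markers_{reason}"] = out.get(f"markers_{reason}", 0) + 1
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "thresholds": self.thresholds,
                    "animals_removed": self.animals_removed,
                    "markers_removed": self.markers_removed,
                    "counts": self.counts(),
                },
                fh,
                indent=2,
            )


def _opposing_homozygote_rate(child: np.ndarray, parent: np.ndarray) -> float:
    both = ~np.isnan(child) & ~np.isnan(parent)
    if not both.any():
        return 0.0
    c, p = child[both], parent[both]
    opp = ((c == 0) & (p == 2)) | ((c == 2) & (p == 0))
    return float(opp.mean())


def qc_genotypes(
    g: GenotypeMatrix,
    ped: Pedigree | None = None,
    animal_miss_max: float = 0.05,
    marker_miss_max: float = 0.05,
    mendel_conflict_max: float = 0.02,
    duplicate_check: bool = True,
    lines: dict[str, str] | None = None,
    monomorphic_scope: str = "combined",
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply QC filters in a fixed order and report every removal.

    Order: (1) animals with missing fraction strictly above ``animal_miss_max``;
    (2) exact duplicate genotype rows (identical calls and missing pattern;
    first by current id order kept); (3) animals whose opposing-homozygote rate
    against any genotyped parent exceeds ``mendel_conflict_max`` (needs
    ``ped``); (4) markers with missing fraction strictly above
    ``marker_miss_max``; (5) monomorphic markers (scope 'combined', or
    'per_line' to drop markers monomorphic within every line of ``lines``).

    Removing entities changes the missingness denominators of the others, so
    the stage sequence is repeated until a full pass removes nothing; the
    result is a fixed point and QC is therefore idempotent.
    """
    for name, t in (("animal_miss_max", animal_miss_max), ("marker_miss_max", marker_miss_max)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    report = QcReport(
        thresholds={
            "animal_miss_max": animal_miss_max,
            "marker_miss_max": marker_miss_max,
            "mendel_conflict_max": mendel_conflict_max,
            "duplicate_check": duplicate_check,
            "monomorphic_scope": monomorphic_scope,
        }
    )
    while True:
        n_before = len(report.animals_removed) + len(report.markers_removed)
        g = _qc_pass(g, ped, animal_miss_max, marker_miss_max, mendel_conflict_max,
                     duplicate_check, lines, monomorphic_scope, report)
        if len(report.animals_removed) + len(report.markers_removed) == n_before:
            return g, report


def _qc_pass(g, ped, animal_miss_max, marker_miss_max, mendel_conflict_max,
             duplicate_check, lines, monomorphic_scope, report) -> GenotypeMatrix:
    # (1) animal missingness
    frac = g.missing_fraction_animals()
    keep = [a for a, f in zip(g.animal_ids, frac) if f <= animal_miss_max]
    for a, f in zip(g.animal_ids, frac):
        if f > animal_miss_max:
            report.animals_removed.append((a, "missingness"))
    g = g.subset(animals=keep)

    # (2) exact duplicates
    if duplicate_check and g.n_animals:
        seen: dict[bytes, str] = {}
        keep = []
        for k, a in enumerate(g.animal_ids):
            key = g.dosages[k].tobytes()  # NaN bit pattern is stable, so missing pattern matches too
            if key in seen:
                report.animals_removed.append((a, "duplicate"))
            else:
                seen[key] = a
                keep.append(a)
        g = g.subset(animals=keep)

    # (3) pedigree-genotype conflicts
    if ped is not None and mendel_conflict_max is not None:
        loc = {a: k for k, a in enumerate(g.animal_ids)}
        keep = []
        for a in g.animal_ids:
            if a not in ped.index:
                keep.append(a)
                continue
            k = ped.index[a]
            worst = 0.0
            for pk in (ped.sire_idx[k], ped.dam_idx[k]):
                if pk >= 0:
                    pid = ped.records[pk].animal_id
                    if pid in loc:
                        worst = max(worst, _opposing_homozygote_rate(g.dosages[loc[a]], g.dosages[loc[pid]]))
            if worst > mendel_conflict_max:
                report.animals_removed.append((a, "pedigree_conflict"))
            else:
                keep.append(a)
        g = g.subset(animals=keep)

    # (4) marker missingness
    mfrac = g.missing_fraction_markers()
    keep_m = [m for m, f in zip(g.marker_ids, mfrac) if f <= marker_miss_max]
    for m, f in zip(g.marker_ids, mfrac):
        if f > marker_miss_max:
            report.markers_removed.append((m, "missingness"))
    g = g.subset(markers=keep_m)

    # (5) monomorphic markers
    def _mono(d: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            mn = np.nanmin(d, axis=0) if d.shape[0] else np.zeros(d.shape[1])
            mx = np.nanmax(d, axis=0) if d.shape[0] else np.zeros(d.shape[1])
        return mn == mx

    if monomorphic_scope == "combined" or not lines:
        mono = _mono(g.dosages)
    elif monomorphic_scope == "per_line":
        by_line: dict[str, list[int]] = {}
        for k, a in enumerate(g.animal_ids):
            by_line.setdefault(lines.get(a, ""), []).append(k)
        mono = np.ones(g.n_markers, dtype=bool)
        for idx in by_line.values():
            mono &= _mono(g.dosages[idx])
    else:
        raise ValueError(f"unknown monomorphic_scope {monomorphic_scope!r}")
    keep_m = [m for m, is_mono in zip(g.marker_ids, mono) if not is_mono]
    for m, is_mono in zip(g.marker_ids, mono):
        if is_mono:
            report.markers_removed.append((m, "monomorphic"))
    return g.subset(markers=keep_m)


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing cell by the marker's mean dosage (unrounded)."""
    d = g.dosages.copy()
    n_obs = np.sum(~np.isnan(d), axis=0)
    if np.any(n_obs == 0):
        bad = [g.marker_ids[k] for k in np.where(n_obs == 0)[0][:5]]
        raise ValueError(f"all-missing marker(s), run QC first: {bad}")
    col_mean = np.nansum(d, axis=0) / n_obs
    miss = np.isnan(d)
    d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
    return GenotypeMatrix(list(g.animal_ids), list(g.marker_ids), g.chrom, g.pos, d)


# ---------------------------------------------------------------------------
# Allele frequencies per cohort


@dataclass
class AfTable:
    """Counted-allele frequency per (line, year) cohort x marker.

    ``p`` has a (line, year) MultiIndex over marker-id columns; ``n_animals``
    is the cohort size per row. ``counted_alleles`` optionally records the
    counted allele per marker so cross-line orientation can be verified.
    """

    p: pd.DataFrame
    n_animals: pd.Series
    counted_alleles: dict[str, str] | None = None

    @property
    def lines(self) -> list[str]:
        return sorted({ln for ln, _ in self.p.index})

    def years(self, line: str) -> list[int]:
        return sorted(y for ln, y in self.p.index if ln == line)

    def freq(self, line: str, year: int) -> pd.Series:
        return self.p.loc[(line, year)]

    def to_long(self) -> pd.DataFrame:
        df = self.p.stack().rename("p").reset_index()
        df.columns = ["line", "year", "marker", "p"]
        return df

    def write_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def allele_freq_by_cohort(
    g: GenotypeMatrix,
    cohorts: dict[int, list[str]],
    line: str = "",
    counted_alleles: dict[str, str] | None = None,
) -> AfTable:
    """p(line, year, marker) = sum(dosage) / (2 x non-missing count)."""
    rows, ns, idx = [], [], []
    for year, ids in sorted(cohorts.items()):
        if not ids:
            logger.warning("empty cohort for year %s omitted", year)
            continue
        rows.append(g.allele_frequencies(animals=list(ids)))
        ns.append(len(ids))
        idx.append((line, year))
    mi = pd.MultiIndex.from_tuples(idx, names=["line", "year"])
    return AfTable(
        pd.DataFrame(rows, index=mi, columns=g.marker_ids),
        pd.Series(ns, index=mi, name="n_animals"),
        counted_alleles=counted_alleles,
    )


def concat_af_tables(tables: list[AfTable]) -> AfTable:
    counted = None
    for t in tables:
        if t.counted_alleles is not None:
            counted = {**(counted or {}), **t.counted_alleles}
    return AfTable(
        pd.concat([t.p for t in tables]),
        pd.concat([t.n_animals for t in tables]),
        counted_alleles=counted,
    )
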