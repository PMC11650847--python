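"""Synthetic breeding populations for end-to-end testing of the pipeline.

The main generator emulates a closed maternal nucleus line under index
truncation selection: overlapping generations (parents used at ages 1-2
years, mean parent age ~1.4 years, matching a generation interval of ~1.4),
seven birth-year cohorts, unlinked biallelic markers with founder frequencies
in Hardy-Weinberg proportions, pleiotropic QTL drawn with a configurable
genetic correlation across traits, phenotypes with batch and litter effects,
and per-year genotyped cohorts. Two lines are independent replicates sharing
the marker map and counted alleles.

Two smaller generators support calibration work: a discrete-generation
random-mating pedigree of constant census size (the idealized population for
drift-variance and Ne checks) and a cross-sectional GWAS cohort with an
optional planted QTL of chosen variance fraction.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, write_dosage_tsv
from .pedigree import Pedigree, PedigreeRecord, write_pedigree

logger = logging.getLogger(__name__)


@dataclass
class TraitSpec:
    name: str
    h2: float
    var_p: float = 1.0

    def __post_init__(self):
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")


@dataclass
class SimConfig:
    n_lines: int = 2
    years: tuple[int, ...] = tuple(range(2015, 2022))
    founders_per_year: int = 300
    sires_per_year: int = 25
    dams_per_year: int = 120
    litter_mean: float = 4.0
    parent_age_probs: dict[int, float] = field(default_factory=lambda: {1: 0.6, 2: 0.4})
    n_markers: int = 2000
    n_qtl: int = 200
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    traits: tuple[TraitSpec, ...] = (TraitSpec("trait1", 0.35), TraitSpec("trait2", 0.20))
    genetic_corr: tuple[tuple[float, ...], ...] | None = None
    index_weights: tuple[float, ...] | None = None
    selection: str = "index_truncation"  # or "random"
    genotyped_fraction: float = 0.6
    batch_var_frac: float = 0.05
    litter_var_frac: float = 0.05
    n_batches_per_year: int = 6

    def __post_init__(self):
        if self.selection not in ("index_truncation", "random"):
            raise ValueError(f"unknown selection mode {self.selection!r}")
        if not 0 < self.genotyped_fraction <= 1:
            raise ValueError("genotyped_fraction must lie in (0, 1]")
        probs = np.array(list(self.parent_age_probs.values()), dtype=float)
        if abs(probs.sum() - 1) > 1e-9:
            raise ValueError("parent_age_probs must sum to 1")
        if self.genetic_corr is None:
            self.genetic_corr = tuple(
                tuple(1.0 if i == j else 0.0 for j in range(len(self.traits)))
                for i in range(len(self.traits))
            )
        C = np.array(self.genetic_corr)
        if np.any(np.linalg.eigvalsh(C) < -1e-9):
            raise ValueError("genetic correlation matrix must be PSD")
        if self.index_weights is None:
            self.index_weights = tuple(1.0 for _ in self.traits)

    @property
    def mean_parent_age(self) -> float:
        return sum(a * p for a, p in self.parent_age_probs.items())


@dataclass
class TrueArchitecture:
    """Planted genetic architecture: pleiotropic QTL over the marker panel."""

    qtl_indices: np.ndarray  # indices into the marker panel
    effects: np.ndarray  # (n_qtl, n_traits) additive effects per counted allele
    trait_names: list[str]
    index_weights: np.ndarray

    @property
    def index_effects(self) -> np.ndarray:
        return self.effects @ self.index_weights

    def breeding_values(self, dosages: np.ndarray) -> np.ndarray:
        """(n_animals, n_traits) true breeding values, centered at dosage 0."""
        return dosages[:, self.qtl_indices] @ self.effects

    def to_json(self, path, marker_ids: list[str]) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "traits": self.trait_names,
                    "index_weights": list(self.index_weights),
                    "qtl": [
                        {
                            "marker": marker_ids[int(k)],
                            "effects": {t: float(self.effects[q, j]) for j, t in enumerate(self.trait_names)},
                        }
                        for q, k in enumerate(self.qtl_indices)
                    ],
                },
                fh,
                indent=2,
            )


def plant_antagonistic_qtl(
    arch: TrueArchitecture, marker_index: int, effects: dict[str, float]
) -> TrueArchitecture:
    """Turn a marker into a pleiotropic QTL with user-given per-trait effects.

    With antagonistic signs and matching index weights the marker's index
    effect can cancel to ~0 — a large single-trait locus invisible to index
    selection.
    """
    eff_row = np.array([effects.get(t, 0.0) for t in arch.trait_names])
    qtl = arch.qtl_indices.copy()
    mat = arch.effects.copy()
    if marker_index in qtl:
        mat[np.where(qtl == marker_index)[0][0]] = eff_row
    else:
        qtl = np.append(qtl, marker_index)
        mat = np.vstack([mat, eff_row])
    return TrueArchitecture(qtl, mat, arch.trait_names, arch.index_weights)


def _draw_architecture(cfg: SimConfig, founder_freqs: np.ndarray, rng: np.random.Generator) -> TrueArchitecture:
    nt = len(cfg.traits)
    qtl = rng.choice(cfg.n_markers, size=cfg.n_qtl, replace=False)
    qtl.sort()
    C = np.array(cfg.genetic_corr, dtype=float)
    raw = rng.multivariate_normal(np.zeros(nt), C, size=cfg.n_qtl, method="cholesky")
    p = founder_freqs[qtl]
    het = 2.0 * p * (1.0 - p)
    eff = np.empty_like(raw)
    for j, tr in enumerate(cfg.traits):
        var_raw = float(np.sum(het * raw[:, j] ** 2))
        target = tr.h2 * tr.var_p
        eff[:, j] = raw[:, j] * np.sqrt(target / var_raw) if var_raw > 0 else 0.0
    return TrueArchitecture(qtl, eff, [t.name for t in cfg.traits], np.array(cfg.index_weights))


@dataclass
class SimResult:
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # genotyped animals only
    phenotypes: pd.DataFrame
    architecture: TrueArchitecture
    marker_freqs_founders: np.ndarray


def _mendelian_offspring(sire_d: np.ndarray, dam_d: np.ndarray, rng) -> np.ndarray:
    """Per-locus gamete sampling for unlinked markers: Bernoulli(dosage/2) each side."""
    return (
        (rng.random(sire_d.shape) < sire_d / 2.0).astype(np.int8)
        + (rng.random(dam_d.shape) < dam_d / 2.0).astype(np.int8)
    )


def simulate_population(
    cfg: SimConfig,
    rng: np.random.Generator,
    arch_hook=None,
) -> SimResult:
    """Simulate one or two closed lines under drift or index truncation.

    ``arch_hook`` may mutate/replace the drawn :class:`TrueArchitecture`
    (e.g. via :func:`plant_antagonistic_qtl`) before breeding starts; the same
    architecture is shared by all lines, which share the marker map and
    counted alleles.
    """
    lo, hi = cfg.founder_maf_range
    founder_freqs = rng.uniform(lo, hi, size=cfg.n_markers)
    arch = _draw_architecture(cfg, founder_freqs, rng)
    if arch_hook is not None:
        arch = arch_hook(arch) or arch
    marker_ids = [f"M{k:05d}" for k in range(cfg.n_markers)]
    # unlinked markers laid out on a nominal map for plotting only
    n_chrom = 10
    per = int(np.ceil(cfg.n_markers / n_chrom))
    chrom = np.array([str(1 + k // per) for k in range(cfg.n_markers)], dtype=object)
    pos = np.array([1000 * (1 + k % per) for k in range(cfg.n_markers)])

    records: list[PedigreeRecord] = []
    all_dosages: list[np.ndarray] = []
    pheno_rows: list[dict] = []
    geno_ids: list[str] = []
    geno_rows: list[int] = []
    nt = len(cfg.traits)
    var_e = np.array(
        [t.var_p * (1 - t.h2 - cfg.batch_var_frac - cfg.litter_var_frac) for t in cfg.traits]
    )
    if np.any(var_e < 0):
        raise ValueError("h2 + batch/litter variance fractions exceed 1")
    ages = sorted(cfg.parent_age_probs)
    first_year = cfg.years[0]
    founder_years = [first_year - a for a in range(max(ages), 0, -1)]

    for line_i in range(cfg.n_lines):
        line = chr(ord("A") + line_i)
        by_year: dict[int, dict] = {}  # year -> {ids, rows, sex, index}
        row_of: dict[str, int] = {}
        counter = 0

        def new_id():
            nonlocal counter
            counter += 1
            return f"{line}{counter:06d}"

        for fy in founder_years:
            n = cfg.founders_per_year
            d = (
                (rng.random((n, cfg.n_markers)) < founder_freqs).astype(np.int8)
                + (rng.random((n, cfg.n_markers)) < founder_freqs).astype(np.int8)
            )
            sex = np.where(rng.random(n) < 0.5, "male", "female")
            ids = []
            for k in range(n):
                aid = new_id()
                ids.append(aid)
                records.append(
                    PedigreeRecord(aid, birth_date=_dt.date(fy, 1, 1), sex=sex[k], line=line)
                )
                row_of[aid] = len(all_dosages)
                all_dosages.append(d[k])
            tbv = arch.breeding_values(d.astype(float))
            index = tbv @ arch.index_weights
            by_year[fy] = dict(ids=ids, sex=sex, index=index)

        for year in cfg.years:
            # candidate pools by age class, with per-age parent quotas
            sel_sires, sel_dams = [], []
            for parent_sex, total, out in (
                ("male", cfg.sires_per_year, sel_sires),
                ("female", cfg.dams_per_year, sel_dams),
            ):
                for a in ages:
                    quota = int(round(total * cfg.parent_age_probs[a]))
                    yb = year - a
                    if yb not in by_year:
                        continue
                    cand = [
                        (i, ix)
                        for i, s, ix in zip(
                            by_year[yb]["ids"], by_year[yb]["sex"], by_year[yb]["index"]
                        )
                        if s == parent_sex
                    ]
                    if len(cand) < quota:
                        raise ValueError(
                            f"infeasible selection: {len(cand)} {parent_sex} candidates born "
                            f"{yb} for quota {quota}"
                        )
                    if cfg.selection == "index_truncation":
                        cand.sort(key=lambda t: -t[1])
                        out.extend(i for i, _ in cand[:quota])
                    else:
                        idxs = rng.choice(len(cand), size=quota, replace=False)
                        out.extend(cand[k][0] for k in idxs)
            n_off_per_dam = np.maximum(1, rng.poisson(cfg.litter_mean, size=len(sel_dams)))
            ids, sexes, indices = [], [], []
            batch_ids = rng.integers(cfg.n_batches_per_year, size=int(n_off_per_dam.sum()))
            batch_eff = {
                j: rng.normal(0, np.sqrt(cfg.batch_var_frac * np.array([t.var_p for t in cfg.traits])),
                              size=nt)
                for j in range(cfg.n_batches_per_year)
            }
            off_i = 0
            for dam, n_off in zip(sel_dams, n_off_per_dam):
                sire = sel_sires[int(rng.integers(len(sel_sires)))]
                litter_id = f"{line}L{year}{dam}"
                litter_eff = rng.normal(
                    0, np.sqrt(cfg.litter_var_frac * np.array([t.var_p for t in cfg.traits]))
                )
                sd = all_dosages[row_of[sire]]
                dd = all_dosages[row_of[dam]]
                d_off = _mendelian_offspring(
                    np.broadcast_to(sd, (n_off, cfg.n_markers)),
                    np.broadcast_to(dd, (n_off, cfg.n_markers)),
                    rng,
                )
                tbv = arch.breeding_values(d_off.astype(float))
                idx_vals = tbv @ arch.index_weights
                for k in range(n_off):
                    aid = new_id()
                    sex = "male" if rng.random() < 0.5 else "female"
                    genotyped = bool(rng.random() < cfg.genotyped_fraction)
                    records.append(
                        PedigreeRecord(
                            aid, sire, dam, _dt.date(year, 1, 1), sex, line, genotyped
                        )
                    )
                    row_of[aid] = len(all_dosages)
                    all_dosages.append(d_off[k])
                    ids.append(aid)
                    sexes.append(sex)
                    indices.append(idx_vals[k])
                    if genotyped:
                        geno_ids.append(aid)
                        geno_rows.append(row_of[aid])
                        pheno = {
                            "animal_id": aid, "line": line, "year": year, "sex": sex,
                            "batch": f"{line}B{year}_{batch_ids[off_i]}", "litter": litter_id,
                        }
                        e = rng.normal(0, np.sqrt(var_e))
                        for j, tr in enumerate(cfg.traits):
                            pheno[tr.name] = float(
                                tbv[k, j] + batch_eff[batch_ids[off_i]][j] + litter_eff[j] + e[j]
                            )
                            pheno[f"tbv_{tr.name}"] = float(tbv[k, j])
                        pheno["index"] = float(idx_vals[k])
                        pheno_rows.append(pheno)
                    off_i += 1
            by_year[year] = dict(ids=ids, sex=np.array(sexes, dtype=object), index=np.array(indices))

    ped = Pedigree(records)
    geno = GenotypeMatrix(
        geno_ids,
        marker_ids,
        chrom,
        pos,
        np.array([all_dosages[r] for r in geno_rows], dtype=float),
    )
    return SimResult(ped, geno, pd.DataFrame(pheno_rows), arch, founder_freqs)


def write_dataset(result: SimResult, out_dir) -> dict[str, str]:
    """Write pedigree CSV, dosage TSV + marker map, phenotype TSV, truth JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": str(out / "pedigree.csv"),
        "genotypes": str(out / "genotypes.tsv"),
        "marker_map": str(out / "marker_map.tsv"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_pedigree(result.pedigree, paths["pedigree"])
    write_dosage_tsv(result.genotypes, paths["genotypes"], marker_map_path=paths["marker_map"])
    result.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    result.architecture.to_json(paths["truth"], result.genotypes.marker_ids)
    return paths


# ---------------------------------------------------------------------------
# Idealized discrete-generation population


def simulate_discrete_pedigree(
    n_males: int, n_females: int, n_generations: int, rng: np.random.Generator,
    start_year: int = 2000,
) -> Pedigree:
    """Constant-size random-mating population with discrete generations.

    Each offspring draws its sire uniformly from the previous generation's
    males and its dam from its females (multinomial family sizes), the
    idealized two-sex population whose effective size is approximately the
    census size. One 'year' = one generation; every animal is genotyped.
    """
    records: list[PedigreeRecord] = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"W{counter:06d}"

    prev_m: list[str] = []
    prev_f: list[str] = []
    for g in range(n_generations + 1):
        cur_m, cur_f = [], []
        for k in range(n_males + n_females):
            sex = "male" if k < n_males else "female"
            aid = new_id()
            if g == 0:
                records.append(
                    PedigreeRecord(aid, birth_date=_dt.date(start_year, 1, 1), sex=sex,
                                   genotyped=True)
                )
            else:
                sire = prev_m[int(rng.integers(len(prev_m)))]
                dam = prev_f[int(rng.integers(len(prev_f)))]
                records.append(
                    PedigreeRecord(aid, sire, dam, _dt.date(start_year + g, 1, 1), sex,
                                   genotyped=True)
                )
            (cur_m if sex == "male" else cur_f).append(aid)
        prev_m, prev_f = cur_m, cur_f
    return Pedigree(records)


# ---------------------------------------------------------------------------
# Cross-sectional GWAS cohort


@dataclass
class GwasCohort:
    genotypes: GenotypeMatrix  # tested markers
    background: GenotypeMatrix | None  # markers feeding the polygenic term (None = tested ones)
    phenotypes: pd.DataFrame  # animal_id, y
    qtl_marker: str | None
    qtl_effect: float
    var_p: float


def simulate_gwas_cohort(
    n_animals: int,
    n_markers: int,
    rng: np.random.Generator,
    h2_polygenic: float = 0.3,
    qtl_variance_frac: float = 0.0,
    n_background: int | None = None,
    maf_range: tuple[float, float] = (0.05, 0.5),
    var_p: float = 1.0,
) -> GwasCohort:
    """Unrelated individuals, unlinked HWE markers, optional planted QTL.

    The polygenic term is built from ``n_background`` separate markers when
    given (so the tested markers are a clean null), otherwise from the tested
    panel itself. One tested marker can be planted as a QTL explaining
    ``qtl_variance_frac`` of the phenotypic variance.
    """
    def draw(n_mk, prefix):
        f = rng.uniform(*maf_range, size=n_mk)
        d = (
            (rng.random((n_animals, n_mk)) < f).astype(float)
            + (rng.random((n_animals, n_mk)) < f).astype(float)
        )
        ids = [f"{prefix}{k:05d}" for k in range(n_mk)]
        return GenotypeMatrix(
            [f"A{i:05d}" for i in range(n_animals)], ids,
            np.array(["1"] * n_mk, dtype=object), np.arange(1, n_mk + 1) * 1000, d,
        ), f

    geno, freqs = draw(n_markers, "M")
    if n_background:
        bg, bg_freqs = draw(n_background, "BG")
        g_src, g_freqs = bg, bg_freqs
    else:
        bg = None
        g_src, g_freqs = geno, freqs
    # polygenic breeding values from small per-marker effects
    m = g_src.n_markers
    a = rng.normal(size=m)
    qtl_marker, qtl_eff = None, 0.0
    qtl_term = 0.0
    k = n_markers // 2
    if qtl_variance_frac > 0 and bg is None:
        a[k] = 0.0  # keep the planted marginal effect exactly at its target
    het = 2 * g_freqs * (1 - g_freqs)
    var_target = h2_polygenic * var_p
    a *= np.sqrt(var_target / np.sum(het * a**2))
    gval = (g_src.dosages - 2 * g_freqs) @ a
    if qtl_variance_frac > 0:
        qtl_marker = geno.marker_ids[k]
        p = freqs[k]
        qtl_eff = float(np.sqrt(qtl_variance_frac * var_p / (2 * p * (1 - p))))
        qtl_term = (geno.dosages[:, k] - 2 * p) * qtl_eff
    var_e = var_p * (1 - h2_polygenic - qtl_variance_frac)
    if var_e <= 0:
        raise ValueError("variance fractions exceed 1")
    y = gval + qtl_term + rng.normal(0, np.sqrt(var_e), size=n_animals)
    pheno = pd.DataFrame({"animal_id": geno.animal_ids, "y": y})
    return GwasCohort(geno, bg, pheno, qtl_marker, qtl_eff, var_p)
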