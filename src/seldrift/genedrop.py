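"""Gene dropping: the pure-drift null for allele-frequency change.

A single biallelic locus is simulated through the observed pedigree. Founders
(both parents unknown) receive two alleles drawn independently as the carrier
allele with probability equal to a set founder MAF (Hardy-Weinberg sampling);
each non-founder inherits one uniformly chosen allele from each parent; an
unknown parent side draws a fresh allele at the founder MAF. Cohort (line,
birth-year) frequencies over the genotyped animals give, across many founder
MAFs and replicates, the drift distribution of allele-frequency change against
a baseline year, to which observed SNP changes are compared conditional on
their realized baseline MAF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree

logger = logging.getLogger(__name__)


def default_maf_grid() -> np.ndarray:
    """Founder MAF grid 0.01 .. 0.50 in steps of 0.01."""
    return np.round(np.arange(1, 51) * 0.01, 2)


@dataclass
class GeneDropConfig:
    cohorts: dict[tuple[str, int], list[str]]  # (line, year) -> genotyped animal ids
    baseline_year: int
    maf_grid: np.ndarray = field(default_factory=default_maf_grid)
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        self.maf_grid = np.asarray(self.maf_grid, dtype=float)
        if np.any((self.maf_grid <= 0) | (self.maf_grid > 0.5)):
            raise ValueError("founder MAF values must lie in (0, 0.5]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.cohorts:
            raise ValueError("cohorts must be non-empty")


@dataclass
class DriftTrajectories:
    """Cohort frequencies per (founder MAF, replicate): shape (n_maf, n_reps, n_cohorts)."""

    maf_grid: np.ndarray
    cohort_keys: list[tuple[str, int]]
    freqs: np.ndarray
    baseline_year: int

    @property
    def lines(self) -> list[str]:
        return sorted({ln for ln, _ in self.cohort_keys})

    def cohort_index(self, line: str, year: int) -> int:
        return self.cohort_keys.index((line, year))


def _pedigree_levels(ped: Pedigree) -> list[np.ndarray]:
    """Group animal indices into levels where all parents sit in earlier levels."""
    n = len(ped)
    depth = np.zeros(n, dtype=np.int64)
    for k in range(n):  # records are topologically ordered
        for pk in (ped.sire_idx[k], ped.dam_idx[k]):
            if pk >= 0:
                depth[k] = max(depth[k], depth[pk] + 1)
    return [np.where(depth == lev)[0] for lev in range(depth.max() + 1)]


def assign_founder_genotypes(ped: Pedigree, maf: float, rng: np.random.Generator) -> dict[str, int]:
    """HW sampling of founder dosages at the given carrier-allele frequency."""
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    return {
        fid: int(rng.random() < maf) + int(rng.random() < maf) for fid in ped.founder_ids
    }


def drop_locus(
    ped: Pedigree,
    founder_genotypes: dict[str, int],
    rng: np.random.Generator,
    maf: float | None = None,
) -> dict[str, int]:
    """Drop one locus through the pedigree by Mendelian transmission.

    ``founder_genotypes`` maps founder id -> dosage. Each non-founder draws one
    uniformly chosen allele from each known parent's pair; an unknown parent
    side draws a fresh allele as carrier with probability ``maf`` (required
    when such half-founders exist).

    This is the scalar (single-replicate) form; :func:`run_gene_dropping`
    vectorizes the same recursion over replicates.
    """
    n = len(ped)
    a1 = np.zeros(n, dtype=np.int8)
    a2 = np.zeros(n, dtype=np.int8)
    for k, rec in enumerate(ped.records):
        sk, dk = ped.sire_idx[k], ped.dam_idx[k]
        if sk < 0 and dk < 0:
            dose = founder_genotypes[rec.animal_id]
            a1[k], a2[k] = (dose + 1) // 2, dose // 2  # split dosage into alleles
            continue
        for slot, pk in ((0, sk), (1, dk)):
            if pk >= 0:
                allele = a1[pk] if rng.random() < 0.5 else a2[pk]
            else:
                if maf is None:
                    raise ValueError("maf required for phantom-parent allele draws")
                allele = int(rng.random() < maf)
            if slot == 0:
                a1[k] = allele
            else:
                a2[k] = allele
    return {rec.animal_id: int(a1[k] + a2[k]) for k, rec in enumerate(ped.records)}


def run_gene_dropping(ped: Pedigree, cfg: GeneDropConfig) -> DriftTrajectories:
    """Run |maf_grid| x n_reps independent gene drops; deterministic given seed.

    Replicates are vectorized within a per-MAF child RNG stream spawned from
    the root seed, so results are reproducible bit-for-bit for a given seed.
    """
    cohort_keys = sorted(cfg.cohorts)
    cohort_idx = []
    for key in cohort_keys:
        ids = cfg.cohorts[key]
        cohort_idx.append(np.array([ped.index[i] for i in ids], dtype=np.int64))
    levels = _pedigree_levels(ped)
    n = len(ped)
    R = cfg.n_reps
    sire = ped.sire_idx
    dam = ped.dam_idx
    is_founder = (sire < 0) & (dam < 0)
    streams = np.random.SeedSequence(cfg.seed).spawn(len(cfg.maf_grid))
    freqs = np.empty((len(cfg.maf_grid), R, len(cohort_keys)))
    for mi, maf in enumerate(cfg.maf_grid):
        rng = np.random.default_rng(streams[mi])
        a1 = np.zeros((n, R), dtype=np.int8)
        a2 = np.zeros((n, R), dtype=np.int8)
        f0 = np.where(is_founder)[0]
        a1[f0] = rng.random((len(f0), R)) < maf
        a2[f0] = rng.random((len(f0), R)) < maf
        for lev in levels[1:]:
            lev = lev[~is_founder[lev]]
            if lev.size == 0:
                continue
            for alleles, par in ((a1, sire[lev]), (a2, dam[lev])):
                known = par >= 0
                rows = lev[known]
                pk = par[known]
                pick = rng.random((len(rows), R)) < 0.5
                dest = a1 if alleles is a1 else a2
                dest[rows] = np.where(pick, a1[pk], a2[pk])
                if (~known).any():
                    dest[lev[~known]] = rng.random(((~known).sum(), R)) < maf
        dose = a1.astype(np.int16) + a2
        for ci, idx in enumerate(cohort_idx):
            freqs[mi, :, ci] = dose[idx].mean(axis=0) / 2.0
    return DriftTrajectories(cfg.maf_grid, cohort_keys, freqs, cfg.baseline_year)


# ---------------------------------------------------------------------------
# Drift envelopes


@dataclass
class DriftEnvelope:
    """Per (line, baseline-MAF bin, horizon year) summaries of |dp| under drift.

    ``table`` columns: line, bin_low, bin_high, horizon_year, n, mean_abs_dp,
    ci_low, ci_high, q95, q99, max, merged. ``samples`` holds the underlying
    replicate |dp| values per (line, bin index, horizon) for quantile lookups.
    """

    table: pd.DataFrame
    samples: dict[tuple[str, int, int], np.ndarray]
    bin_edges: dict[str, list[tuple[float, float]]]
    baseline_year: int

    def bin_of(self, line: str, maf: float) -> int:
        """Index of the (merged) bin containing a folded baseline MAF; nearest bin if outside."""
        edges = self.bin_edges[line]
        for k, (lo, hi) in enumerate(edges):
            if lo < maf <= hi:
                return k
        centers = np.array([(lo + hi) / 2 for lo, hi in edges])
        return int(np.argmin(np.abs(centers - maf)))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def drift_change_distribution(
    traj: DriftTrajectories,
    baseline_year: int | None = None,
    bin_width: float = 0.01,
    min_reps: int = 30,
) -> DriftEnvelope:
    """Bin replicates by realized baseline-cohort MAF and summarize |dp|.

    All (founder MAF, replicate) pairs are pooled, then binned by the folded
    frequency their trajectory realized in the baseline-year cohort — the
    observed SNPs are conditioned on their baseline MAF, so the null is
    conditioned the same way. Replicates fixed at baseline (MAF exactly 0)
    cannot correspond to a segregating SNP and are excluded. Bins with fewer
    than ``min_reps`` replicates are merged with their right neighbour (the
    last bin merges left) and flagged.
    """
    baseline_year = traj.baseline_year if baseline_year is None else baseline_year
    rows = []
    samples: dict[tuple[str, int, int], np.ndarray] = {}
    bin_edges: dict[str, list[tuple[float, float]]] = {}
    for line in traj.lines:
        years = sorted(y for ln, y in traj.cohort_keys if ln == line)
        if baseline_year not in years:
            raise ValueError(f"baseline year {baseline_year} absent for line {line!r}")
        b_ci = traj.cohort_index(line, baseline_year)
        pb = traj.freqs[:, :, b_ci].ravel()
        maf_b = np.minimum(pb, 1.0 - pb)
        n_bins = int(np.ceil(0.5 / bin_width))
        raw_bin = np.clip(np.ceil(maf_b / bin_width).astype(int) - 1, 0, n_bins - 1)
        seg = maf_b > 0
        counts = np.bincount(raw_bin[seg], minlength=n_bins)
        # merge small bins rightwards
        groups: list[list[int]] = []
        cur: list[int] = []
        cur_n = 0
        for k in range(n_bins):
            cur.append(k)
            cur_n += counts[k]
            if cur_n >= min_reps:
                groups.append(cur)
                cur, cur_n = [], 0
        if cur:
            if groups:
                groups[-1].extend(cur)
            else:
                groups.append(cur)
        edges = [(g[0] * bin_width, (g[-1] + 1) * bin_width) for g in groups]
        bin_edges[line] = edges
        group_of = np.empty(n_bins, dtype=int)
        for gi, g in enumerate(groups):
            group_of[g] = gi
        rep_bin = np.where(seg, group_of[raw_bin], -1)
        for gi, (lo, hi) in enumerate(edges):
            in_bin = rep_bin == gi
            n_in = int(in_bin.sum())
            merged = len(groups[gi]) > 1
            for year in years:
                ci = traj.cohort_index(line, year)
                dp = np.abs(traj.freqs[:, :, ci].ravel()[in_bin] - pb[in_bin])
                samples[(line, gi, year)] = dp
                if n_in:
                    mean = float(dp.mean())
                    se = float(dp.std(ddof=1) / np.sqrt(n_in)) if n_in > 1 else 0.0
                    qs = np.quantile(dp, [0.95, 0.99]) if n_in else (np.nan, np.nan)
                    rows.append(
                        dict(
                            line=line, bin_low=lo, bin_high=hi, horizon_year=year, n=n_in,
                            mean_abs_dp=mean, ci_low=mean - 1.96 * se, ci_high=mean + 1.96 * se,
                            q95=float(qs[0]), q99=float(qs[1]), max=float(dp.max()), merged=merged,
                        )
                    )
                else:
                    rows.append(
                        dict(line=line, bin_low=lo, bin_high=hi, horizon_year=year, n=0,
                             mean_abs_dp=np.nan, ci_low=np.nan, ci_high=np.nan,
                             q95=np.nan, q99=np.nan, max=np.nan, merged=merged)
                    )
    return DriftEnvelope(pd.DataFrame(rows), samples, bin_edges, baseline_year)


# ---------------------------------------------------------------------------
# Observed-vs-drift comparison


@dataclass
class ComparisonReport:
    per_snp: pd.DataFrame
    per_bin: pd.DataFrame
    summary: dict


def compare_to_drift(observed, env: DriftEnvelope) -> ComparisonReport:
    """Compare observed per-SNP |dp| (an AfChangeTable frame) against drift.

    ``observed`` is a long DataFrame with columns line, marker, year, abs_dp,
    baseline_maf (as produced by ``afdynamics.abs_change_vs_baseline``). Per
    SNP: its bin, the envelope quantile its |dp| falls at, and whether it
    exceeds the bin maximum. Per bin and horizon: a two-sided z test of the
    observed mean |dp| against the drift mean.
    """
    obs = observed.frame if hasattr(observed, "frame") else observed
    snp_rows = []
    for line, marker, year, adp, maf_b in obs[
        ["line", "marker", "year", "abs_dp", "baseline_maf"]
    ].itertuples(index=False):
        if maf_b <= 0 or not np.isfinite(maf_b):
            continue
        gi = env.bin_of(line, maf_b)
        key = (line, gi, int(year))
        if key not in env.samples:
            continue
        smp = env.samples[key]
        flagged = not (env.bin_edges[line][gi][0] < maf_b <= env.bin_edges[line][gi][1])
        if smp.size:
            quant = float(np.mean(smp <= adp))
            exceeds = bool(adp > smp.max())
        else:
            quant, exceeds = np.nan, False
        snp_rows.append(
            dict(line=line, marker=marker, year=int(year), abs_dp=adp, baseline_maf=maf_b,
                 bin=gi, drift_quantile=quant, exceeds_max=exceeds, nearest_bin_used=flagged)
        )
    per_snp = pd.DataFrame(snp_rows)
    bin_rows = []
    if len(per_snp):
        for (line, gi, year), grp in per_snp.groupby(["line", "bin", "year"]):
            smp = env.samples[(line, gi, year)]
            if smp.size < 2 or len(grp) < 2:
                continue
            m_obs, m_drift = grp["abs_dp"].mean(), smp.mean()
            se = np.sqrt(grp["abs_dp"].var(ddof=1) / len(grp) + smp.var(ddof=1) / smp.size)
            z = (m_obs - m_drift) / se if se > 0 else 0.0
            bin_rows.append(
                dict(line=line, bin=gi, year=year, n_snps=len(grp), obs_mean_abs_dp=m_obs,
                     drift_mean_abs_dp=m_drift, z=z, p=2 * stats.norm.sf(abs(z)))
            )
    per_bin = pd.DataFrame(bin_rows)
    summary = {
        "n_snps": int(len(per_snp)),
        "n_exceed_max": int(per_snp["exceeds_max"].sum()) if len(per_snp) else 0,
        "largest_changes_within_drift": bool(per_snp["exceeds_max"].sum() == 0) if len(per_snp) else True,
        "frac_bins_obs_mean_above_drift": float(
            np.mean(per_bin["obs_mean_abs_dp"] > per_bin["drift_mean_abs_dp"])
        ) if len(per_bin) else float("nan"),
    }
    return ComparisonReport(per_snp, per_bin, summary)
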