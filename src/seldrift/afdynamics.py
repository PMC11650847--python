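"""Allele-frequency-change analytics.

Changes are expressed against a baseline birth-year cohort (|dp| versus
baseline), stratified by the baseline minor allele frequency, regressed on
GWAS effect sizes and significance from the same year, correlated between
lines, and plotted as minor-allele-oriented trajectories for significant
regions. Absolute-change statistics are invariant to allele recoding; signed
statistics flip sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import AfTable
from .gwas import GwasResult

logger = logging.getLogger(__name__)

DEFAULT_MAF_STRATA = ((0.0, 0.05), (0.05, 0.1), (0.1, 0.2), (0.2, 0.5))
"""Baseline-MAF strata (lo, hi], closed on the right edge."""


@dataclass
class AfChangeTable:
    """Long table of per (line, marker, year) frequency changes vs baseline.

    Columns: line, marker, year, p_year, p_baseline, dp, abs_dp, baseline_maf
    (folded to <= 0.5).
    """

    frame: pd.DataFrame
    baseline_year: int
    counted_alleles: dict[str, str] | None = None

    def for_line(self, line: str) -> pd.DataFrame:
        return self.frame[self.frame["line"] == line]

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def abs_change_vs_baseline(af: AfTable, baseline_year: int) -> AfChangeTable:
    """dp and |dp| per marker and year against the baseline-year cohort."""
    rows = []
    for line in af.lines:
        years = af.years(line)
        if baseline_year not in years:
            raise ValueError(f"baseline year {baseline_year} absent for line {line!r}")
        pb = af.freq(line, baseline_year)
        present = pb.notna()
        if (~present).any():
            logger.warning("%d markers absent in baseline dropped for line %s", (~present).sum(), line)
        maf_b = np.minimum(pb, 1.0 - pb)
        for year in years:
            py = af.freq(line, year)
            df = pd.DataFrame(
                {
                    "line": line,
                    "marker": af.p.columns,
                    "year": year,
                    "p_year": py.to_numpy(),
                    "p_baseline": pb.to_numpy(),
                    "dp": (py - pb).to_numpy(),
                    "abs_dp": np.abs((py - pb).to_numpy()),
                    "baseline_maf": maf_b.to_numpy(),
                }
            )
            rows.append(df[present.to_numpy()])
    return AfChangeTable(
        pd.concat(rows, ignore_index=True), baseline_year, counted_alleles=af.counted_alleles
    )


def consecutive_year_change(af: AfTable, line: str, year: int) -> pd.DataFrame:
    """|dp| from birth-year cohort ``year`` to ``year + 1`` for one line."""
    years = af.years(line)
    if year not in years or year + 1 not in years:
        raise ValueError(f"need cohorts for {year} and {year + 1} in line {line!r}")
    p0, p1 = af.freq(line, year), af.freq(line, year + 1)
    return pd.DataFrame(
        {
            "marker": af.p.columns,
            "dp": (p1 - p0).to_numpy(),
            "abs_dp": np.abs((p1 - p0).to_numpy()),
            "maf": np.minimum(p0, 1 - p0).to_numpy(),
        }
    )


def maf_stratified_summary(
    chg: AfChangeTable,
    strata: tuple[tuple[float, float], ...] = DEFAULT_MAF_STRATA,
    quantiles: tuple[float, ...] = (0.5, 0.95, 0.99),
) -> pd.DataFrame:
    """Max and distribution of |dp| per baseline-MAF stratum and horizon year.

    Strata are (lo, hi] with a closed right edge; a marker with baseline MAF
    exactly 0.05 falls in the first stratum. Empty strata report count 0.
    """
    rows = []
    for (line, year), grp in chg.frame.groupby(["line", "year"]):
        for lo, hi in strata:
            sel = grp[(grp["baseline_maf"] > lo) & (grp["baseline_maf"] <= hi)]
            row = dict(line=line, year=year, maf_low=lo, maf_high=hi, n=len(sel))
            if len(sel):
                row["max_abs_dp"] = float(sel["abs_dp"].max())
                for q in quantiles:
                    row[f"q{int(q * 100)}"] = float(sel["abs_dp"].quantile(q))
            else:
                row["max_abs_dp"] = np.nan
                for q in quantiles:
                    row[f"q{int(q * 100)}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ChangeGwasRegression:
    """OLS of next-year |dp| on |effect| and on -log10 p."""

    line: str
    trait: str
    year: int
    n_markers: int
    maf_min: float
    slope_effect: float
    r2_effect: float
    slope_neglogp: float
    r2_neglogp: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _ols_1d(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    vx = np.var(x)
    if vx == 0:
        return 0.0, 0.0, True
    slope = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    r = np.corrcoef(x, y)[0, 1]
    return slope, float(r * r), False


def change_vs_gwas_regression(
    next_year_change: pd.DataFrame,
    res: GwasResult,
    line: str = "",
    year: int = 0,
    maf_min: float = 0.0,
) -> ChangeGwasRegression:
    """Regress year-to-next-year |dp| on the year's GWAS |effect| and -log10 p.

    ``next_year_change`` comes from :func:`consecutive_year_change`. Markers
    with analysis-set MAF below ``maf_min`` are excluded. Mirrors the check
    that frequency changes over one generation are unrelated to estimated
    effects or significance.
    """
    gw = res.frame[["marker", "effect", "neglog10p", "maf"]].dropna()
    merged = next_year_change.merge(gw, on="marker")
    merged = merged[merged["maf_y"] >= maf_min] if "maf_y" in merged else merged[merged["maf"] >= maf_min]
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared markers between change table and GWAS")
    adp = merged["abs_dp"].to_numpy()
    s_eff, r2_eff, d1 = _ols_1d(np.abs(merged["effect"].to_numpy()), adp)
    s_sig, r2_sig, d2 = _ols_1d(merged["neglog10p"].to_numpy(), adp)
    return ChangeGwasRegression(
        line=line, trait=res.trait, year=year, n_markers=len(merged), maf_min=maf_min,
        slope_effect=s_eff, r2_effect=r2_eff, slope_neglogp=s_sig, r2_neglogp=r2_sig,
        degenerate=d1 or d2,
    )


def between_line_correlation(
    chg_a: AfChangeTable, chg_b: AfChangeTable, year: int, signed: bool = True
) -> float:
    """Squared Pearson correlation of (signed) dp between two lines at a horizon.

    Requires counted-allele metadata on both tables with matching orientation
    per marker; a silent flip would corrupt the sign of the correlation.
    """
    if chg_a.counted_alleles is None or chg_b.counted_alleles is None:
        raise ValueError("counted-allele orientation metadata required on both change tables")
    a = chg_a.frame[chg_a.frame["year"] == year].set_index("marker")
    b = chg_b.frame[chg_b.frame["year"] == year].set_index("marker")
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("no shared markers between lines")
    mismatched = [m for m in shared if chg_a.counted_alleles.get(m) != chg_b.counted_alleles.get(m)]
    if mismatched:
        raise ValueError(f"counted-allele orientation differs between lines for {mismatched[:5]}")
    col = "dp" if signed else "abs_dp"
    r = np.corrcoef(a.loc[shared, col], b.loc[shared, col])[0, 1]
    return float(r * r)


def trajectory_of_significant(
    af: AfTable,
    res: GwasResult,
    line: str,
    chrom: str,
    start: int,
    end: int,
    threshold: float,
    baseline_year: int,
) -> tuple[pd.DataFrame, str]:
    """Yearly frequencies of significant SNPs in a region, minor-allele oriented.

    Frequencies are flipped so the allele that was below 0.5 in the baseline
    year is tracked (a baseline frequency of exactly 0.5 keeps the counted
    allele). Returns (long frame with columns marker, year, freq, neglog10p),
    and the lead SNP id (max -log10 p, ties broken by smaller position).
    """
    reg = res.frame[
        (res.frame["chrom"].astype(str) == str(chrom))
        & (res.frame["pos"] >= start)
        & (res.frame["pos"] <= end)
    ]
    sig = reg[reg["neglog10p"] >= threshold]
    if sig.empty:
        raise ValueError("no significant markers in the requested region")
    pb = af.freq(line, baseline_year)
    rows = []
    for marker, nlp in zip(sig["marker"], sig["neglog10p"]):
        flip = pb[marker] > 0.5
        for year in af.years(line):
            p = af.freq(line, year)[marker]
            rows.append(dict(marker=marker, year=year, freq=1.0 - p if flip else p, neglog10p=nlp))
    lead = sig.sort_values(["neglog10p", "pos"], ascending=[False, True]).iloc[0]["marker"]
    return pd.DataFrame(rows), str(lead)
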