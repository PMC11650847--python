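"""Pedigree handling, additive relationships, and effective population size.

The effective population size of a pedigreed population is estimated from the
rate of pedigree inbreeding: mean kinship f_t among the genotyped animals born
in year t is computed as half the average off-diagonal of the numerator
relationship matrix A, ln(1 - f_t) is regressed on calendar year, the rate of
inbreeding per year is dF_year = 1 - exp(b), per generation dF_L = L * dF_year
with L the generation interval (mean parent age at offspring birth), and
Ne = 1 / (2 * dF_L).
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = ""
"""Sentinel for an unknown parent."""

_UNKNOWN_TOKENS = {"", "0", "NA", "na", "NaN", "nan", ".", "None"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class PedigreeRecord:
    animal_id: str
    sire_id: str = UNKNOWN
    dam_id: str = UNKNOWN
    birth_date: _dt.date | None = None
    sex: str = "unknown"  # {male, female, unknown}
    line: str = ""
    genotyped: bool = False

    @property
    def birth_year(self) -> int | None:
        return None if self.birth_date is None else self.birth_date.year


class Pedigree:
    """A validated, topologically ordered pedigree.

    Invariants enforced at construction: unique animal ids, acyclicity, and
    (unless ``allow_age_conflicts``) parents born strictly before offspring
    whenever both dates are known. Records are stored in a topological order
    (parents before offspring).
    """

    def __init__(self, records: list[PedigreeRecord], allow_age_conflicts: bool = False):
        ids = [r.animal_id for r in records]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate animal id: {i!r}")
            seen.add(i)
        index = {r.animal_id: k for k, r in enumerate(records)}
        # check parent references resolve
        for r in records:
            for p in (r.sire_id, r.dam_id):
                if p != UNKNOWN and p not in index:
                    raise PedigreeError(
                        f"parent id {p!r} of {r.animal_id!r} not present; "
                        "use read_pedigree/add_missing_founders to auto-add founders"
                    )
        order = self._toposort(records, index)
        self.records: list[PedigreeRecord] = [records[k] for k in order]
        self.index: dict[str, int] = {r.animal_id: k for k, r in enumerate(self.records)}
        n = len(self.records)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for k, r in enumerate(self.records):
            if r.sire_id != UNKNOWN:
                self.sire_idx[k] = self.index[r.sire_id]
            if r.dam_id != UNKNOWN:
                self.dam_idx[k] = self.index[r.dam_id]
        # birth-order sanity
        for k, r in enumerate(self.records):
            for pk in (self.sire_idx[k], self.dam_idx[k]):
                if pk >= 0:
                    pb = self.records[pk].birth_date
                    if pb is not None and r.birth_date is not None and pb >= r.birth_date:
                        msg = (
                            f"parent {self.records[pk].animal_id!r} born {pb} not before "
                            f"offspring {r.animal_id!r} born {r.birth_date}"
                        )
                        if allow_age_conflicts:
                            warnings.warn(msg)
                        else:
                            raise PedigreeError(msg)

    @staticmethod
    def _toposort(records: list[PedigreeRecord], index: dict[str, int]) -> list[int]:
        n = len(records)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = [0] * n
        for k, r in enumerate(records):
            for p in (r.sire_id, r.dam_id):
                if p != UNKNOWN:
                    children[index[p]].append(k)
                    indeg[k] += 1
        queue = [k for k in range(n) if indeg[k] == 0]
        out: list[int] = []
        while queue:
            k = queue.pop()
            out.append(k)
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(out) != n:
            cyc = Pedigree._find_cycle(records, index)
            raise PedigreeError(f"pedigree contains a cycle: {' -> '.join(cyc)}")
        return out

    @staticmethod
    def _find_cycle(records, index) -> list[str]:
        color = {}  # 0 absent, 1 on stack, 2 done

        def parents(k):
            r = records[k]
            return [index[p] for p in (r.sire_id, r.dam_id) if p != UNKNOWN]

        for start in range(len(records)):
            stack = [(start, iter(parents(start)))]
            path = [start]
            color[start] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if color.get(p, 0) == 1:
                        i = path.index(p)
                        return [records[x].animal_id for x in path[i:] + [p]]
                    if color.get(p, 0) == 0:
                        color[p] = 1
                        path.append(p)
                        stack.append((p, iter(parents(p))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = 2
                    path.pop()
                    stack.pop()
        return ["<cycle>"]

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self.index

    @property
    def animal_ids(self) -> list[str]:
        return [r.animal_id for r in self.records]

    def is_founder(self, animal_id: str) -> bool:
        """Founder = both parents unknown."""
        k = self.index[animal_id]
        return self.sire_idx[k] < 0 and self.dam_idx[k] < 0

    @property
    def founder_ids(self) -> list[str]:
        return [
            r.animal_id
            for k, r in enumerate(self.records)
            if self.sire_idx[k] < 0 and self.dam_idx[k] < 0
        ]

    def genotyped_ids(self, line: str | None = None) -> list[str]:
        return [
            r.animal_id
            for r in self.records
            if r.genotyped and (line is None or r.line == line)
        ]

    def cohorts(self, line: str | None = None, genotyped_only: bool = True) -> dict[int, list[str]]:
        """Birth-year cohorts (genotyped animals by default), per line."""
        out: dict[int, list[str]] = {}
        for r in self.records:
            if genotyped_only and not r.genotyped:
                continue
            if line is not None and r.line != line:
                continue
            if r.birth_year is None:
                continue
            out.setdefault(r.birth_year, []).append(r.animal_id)
        return dict(sorted(out.items()))

    @property
    def lines(self) -> list[str]:
        return sorted({r.line for r in self.records if r.line})

    def ancestor_closure(self, ids: list[str]) -> list[str]:
        """All requested animals plus their ancestors, in topological order."""
        for i in ids:
            if i not in self.index:
                raise PedigreeError(f"animal id not in pedigree: {i!r}")
        keep = np.zeros(len(self), dtype=bool)
        for i in ids:
            keep[self.index[i]] = True
        # records are topologically ordered, so one reverse sweep suffices
        for k in range(len(self) - 1, -1, -1):
            if keep[k]:
                for pk in (self.sire_idx[k], self.dam_idx[k]):
                    if pk >= 0:
                        keep[pk] = True
        return [self.records[k].animal_id for k in range(len(self)) if keep[k]]

    # -- relationships ---------------------------------------------------
    def additive_relationship(self, ids: list[str]) -> pd.DataFrame:
        """Numerator relationship matrix A restricted to ``ids``.

        Computed by the tabular method over the ancestor closure of the
        requested subset (provably identical to using the full pedigree).
        Diagonal entries are 1 + F_i with F_i the inbreeding coefficient;
        an unknown parent side contributes as an unrelated non-inbred founder.
        """
        closure = self.ancestor_closure(ids)
        n = len(closure)
        loc = {a: k for k, a in enumerate(closure)}
        s = np.full(n, -1, dtype=np.int64)
        d = np.full(n, -1, dtype=np.int64)
        for k, a in enumerate(closure):
            gk = self.index[a]
            if self.sire_idx[gk] >= 0:
                s[k] = loc[self.records[self.sire_idx[gk]].animal_id]
            if self.dam_idx[gk] >= 0:
                d[k] = loc[self.records[self.dam_idx[gk]].animal_id]
        A = np.zeros((n, n))
        for k in range(n):
            sk, dk = s[k], d[k]
            row = np.zeros(k)
            if sk >= 0:
                row += 0.5 * A[sk, :k]
            if dk >= 0:
                row += 0.5 * A[dk, :k]
            A[k, :k] = row
            A[:k, k] = row
            A[k, k] = 1.0 + (0.5 * A[sk, dk] if sk >= 0 and dk >= 0 else 0.0)
        sel = [loc[i] for i in ids]
        sub = A[np.ix_(sel, sel)]
        return pd.DataFrame(sub, index=list(ids), columns=list(ids))


# ---------------------------------------------------------------------------
# IO


@dataclass
class PedigreeReadReport:
    n_records: int = 0
    auto_added_founders: list[str] = field(default_factory=list)


def _parse_date(tok) -> _dt.date | None:
    if tok is None:
        return None
    tok = str(tok).strip()
    if tok in _UNKNOWN_TOKENS:
        return None
    if len(tok) == 4 and tok.isdigit():  # bare year
        return _dt.date(int(tok), 1, 1)
    try:
        return _dt.date.fromisoformat(tok[:10])
    except ValueError as e:
        raise PedigreeError(f"unparseable birth date: {tok!r}") from e


_DEFAULT_COLUMNS = {
    "id": "id",
    "sire": "sire",
    "dam": "dam",
    "birth_date": "birth_date",
    "sex": "sex",
    "line": "line",
    "genotyped": "genotyped",
}


def read_pedigree(
    path,
    columns: dict[str, str] | None = None,
    allow_age_conflicts: bool = False,
) -> tuple[Pedigree, PedigreeReadReport]:
    """Read a pedigree CSV into a validated :class:`Pedigree`.

    ``columns`` maps the roles id/sire/dam/birth_date/sex/line/genotyped to the
    file's column names (defaults shown in ``_DEFAULT_COLUMNS``). Parent ids
    "0", "" and "NA" parse as unknown. Parents referenced but absent from the
    id column are auto-added as founders with unknown birth date and reported.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for role in ("id", "sire", "dam", "birth_date"):
        if cols[role] not in df.columns:
            raise PedigreeError(f"column {cols[role]!r} (role {role}) missing from {path}")

    def norm_parent(tok: str) -> str:
        return UNKNOWN if str(tok).strip() in _UNKNOWN_TOKENS else str(tok).strip()

    records: list[PedigreeRecord] = []
    known_ids = set(df[cols["id"]].astype(str).str.strip())
    report = PedigreeReadReport()
    for _, row in df.iterrows():
        sex = str(row[cols["sex"]]).strip().lower() if cols["sex"] in df.columns else "unknown"
        if sex in ("m", "male", "1"):
            sex = "male"
        elif sex in ("f", "female", "2"):
            sex = "female"
        else:
            sex = "unknown"
        genotyped = False
        if cols["genotyped"] in df.columns:
            genotyped = str(row[cols["genotyped"]]).strip() in ("1", "true", "True")
        records.append(
            PedigreeRecord(
                animal_id=str(row[cols["id"]]).strip(),
                sire_id=norm_parent(row[cols["sire"]]),
                dam_id=norm_parent(row[cols["dam"]]),
                birth_date=_parse_date(row[cols["birth_date"]]),
                sex=sex,
                line=str(row[cols["line"]]).strip() if cols["line"] in df.columns else "",
                genotyped=genotyped,
            )
        )
    referenced = {r.sire_id for r in records} | {r.dam_id for r in records}
    referenced.discard(UNKNOWN)
    missing = sorted(referenced - known_ids)
    for m in missing:
        records.append(PedigreeRecord(animal_id=m))
        report.auto_added_founders.append(m)
    if missing:
        logger.warning("auto-added %d founder records for referenced parents", len(missing))
    report.n_records = len(records)
    return Pedigree(records, allow_age_conflicts=allow_age_conflicts), report


def write_pedigree(ped: Pedigree, path) -> None:
    rows = [
        {
            "id": r.animal_id,
            "sire": r.sire_id if r.sire_id != UNKNOWN else "0",
            "dam": r.dam_id if r.dam_id != UNKNOWN else "0",
            "birth_date": r.birth_date.isoformat() if r.birth_date else "NA",
            "sex": r.sex,
            "line": r.line,
            "genotyped": int(r.genotyped),
        }
        for r in ped.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Kinship series, generation interval, Ne


@dataclass
class KinshipSeries:
    """Mean pedigree kinship f_t per calendar year (unordered-pair average)."""

    years: np.ndarray  # int years
    f: np.ndarray  # f_t in [0, 1]
    n_pairs: np.ndarray  # m(m-1)/2 unordered pairs per cohort
    line: str | None = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.f = np.asarray(self.f, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any((self.f < 0) | (self.f > 1)):
            raise ValueError("f_t outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "f_t": self.f, "n_pairs": self.n_pairs})


def mean_kinship_by_year(
    ped: Pedigree,
    years: list[int] | None = None,
    line: str | None = None,
    genotyped_only: bool = True,
) -> KinshipSeries:
    """f_t = 0.5 x mean off-diagonal A among the cohort born in year t.

    Cohorts with fewer than 2 animals are dropped with a logged warning.
    """
    cohorts = ped.cohorts(line=line, genotyped_only=genotyped_only)
    if years is not None:
        cohorts = {y: cohorts.get(y, []) for y in years}
    all_ids = [i for ids in cohorts.values() for i in ids]
    if not all_ids:
        raise PedigreeError("no cohort members found")
    A = ped.additive_relationship(all_ids).to_numpy()
    loc = {a: k for k, a in enumerate(all_ids)}
    out_years, out_f, out_np = [], [], []
    for y, ids in cohorts.items():
        m = len(ids)
        if m < 2:
            logger.warning("year %s dropped: cohort size %d < 2", y, m)
            continue
        sel = np.array([loc[i] for i in ids])
        block = A[np.ix_(sel, sel)]
        iu = np.triu_indices(m, k=1)
        out_years.append(y)
        out_f.append(0.5 * float(block[iu].mean()))
        out_np.append(m * (m - 1) // 2)
    return KinshipSeries(np.array(out_years), np.array(out_f), np.array(out_np), line=line)


def generation_interval(
    ped: Pedigree, ids: list[str] | None = None
) -> tuple[float, dict]:
    """Mean parent age (years) over all (offspring, known parent) links.

    Links where either birth date is missing are skipped and counted in the
    returned report dict.
    """
    ids = ids if ids is not None else ped.animal_ids
    gaps = []
    skipped = 0
    for i in ids:
        k = ped.index[i]
        ob = ped.records[k].birth_date
        for pk in (ped.sire_idx[k], ped.dam_idx[k]):
            if pk < 0:
                continue
            pb = ped.records[pk].birth_date
            if ob is None or pb is None:
                skipped += 1
                continue
            gaps.append((ob - pb).days / 365.25)
    if not gaps:
        raise PedigreeError("no usable offspring-parent links with known birth dates")
    return float(np.mean(gaps)), {"n_links": len(gaps), "n_skipped": skipped}


@dataclass
class NeEstimate:
    """Effective population size from the rate of pedigree inbreeding.

    slope_b is the OLS coefficient of ln(1 - f_t) on calendar year;
    delta_f_year = 1 - exp(slope_b); delta_f_gen = L * delta_f_year;
    ne = 1 / (2 * delta_f_gen). ``defined`` is False when kinship is
    non-increasing (delta_f_gen <= 0), in which case ne is NaN.
    """

    slope_b: float
    delta_f_year: float
    generation_interval_L: float
    delta_f_gen: float
    ne: float
    n_years: int
    defined: bool = True
    line: str | None = None

    @property
    def ne_rounded(self) -> int | None:
        """Display value, rounded half-to-even."""
        return None if not self.defined else round(self.ne)

    def to_dict(self) -> dict:
        return {
            "line": self.line,
            "slope_b": self.slope_b,
            "delta_f_year": self.delta_f_year,
            "generation_interval_L": self.generation_interval_L,
            "delta_f_gen": self.delta_f_gen,
            "ne": self.ne,
            "ne_rounded": self.ne_rounded,
            "n_years": self.n_years,
            "defined": self.defined,
        }


def estimate_ne(series: KinshipSeries, L: float) -> NeEstimate:
    """OLS of ln(1 - f_t) on year, then Ne = 1 / (2 L (1 - exp(b)))."""
    if len(series.years) < 3:
        raise ValueError("need at least 3 yearly cohorts to regress")
    if np.any(series.f >= 1):
        raise ValueError("f_t must be < 1")
    y = np.log1p(-series.f)
    b = float(np.polyfit(series.years.astype(float), y, 1)[0])
    df_year = 1.0 - float(np.exp(b))
    df_gen = L * df_year
    if df_gen <= 0:
        return NeEstimate(b, df_year, L, df_gen, float("nan"), len(series.years), False, series.line)
    return NeEstimate(b, df_year, L, df_gen, 1.0 / (2.0 * df_gen), len(series.years), True, series.line)
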