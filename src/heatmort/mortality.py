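"""ICD-10 cause-of-death grouping and daily mortality series.

Deaths are classified by underlying cause into 15 specific groups possibly
related to heat (respiratory, circulatory, neoplasms, dementia, diabetes,
renal, sepsis, urinary, unspecified) plus two aggregates: "selected"
(any specific group) and "natural" (everything except external causes).
Series are built per cause group and age band (0-64 / 65+), zero-filled
over the study window, and summarized; series with a daily median <= 1 or
more than 20 % zero days are too sparse to model, and series with
variance/mean above 1.6 are fitted with a quasipoisson likelihood.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CauseGroupDef",
    "CAUSE_GROUPS",
    "CauseSeries",
    "normalize_icd",
    "classify_icd",
    "build_series",
    "eligibility",
    "choose_likelihood",
    "summary_table",
    "read_deaths_csv",
]

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]?$")


def normalize_icd(code: str) -> str:
    """Upper-case, strip the dot; error on anything not shaped like ICD-10."""
    c = str(code).strip().upper().replace(".", "")
    if not _ICD_RE.match(c):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return c


@dataclass(frozen=True)
class CauseGroupDef:
    """A cause group as a list of inclusive code intervals (single codes are
    degenerate intervals).  A 3-character endpoint covers its 4-character
    children (I15 covers I159)."""

    name: str
    ranges: tuple[tuple[str, str], ...]
    is_aggregate: bool = False

    def matches(self, code: str) -> bool:
        for start, end in self.ranges:
            if code >= start and code[: len(end)] <= end:
                return True
        return False


def _rng(spec: str) -> tuple[str, str]:
    if "-" in spec:
        a, b = spec.split("-")
        a, b = a.replace(".", ""), b.replace(".", "")
        if a[0] != b[0] and not a < b:
            raise ValueError(f"bad range {spec}")
        return a, b
    c = spec.replace(".", "")
    return c, c


def _group(name: str, *specs: str) -> CauseGroupDef:
    return CauseGroupDef(name, tuple(_rng(s) for s in specs))


CAUSE_GROUPS: tuple[CauseGroupDef, ...] = (
    _group("Influenza and pneumonia", "J09-J18"),
    _group("Chronic lower respiratory diseases", "J40-J47"),
    _group("Other diseases of the respiratory system",
           "J00-J06", "J20-J39", "J60-J70", "J80-J86", "J90-J96", "J97-J99",
           "R09.2", "U04"),
    _group("Hypertensive diseases", "I10-I15"),
    _group("Ischemic heart disease", "I20-I25"),
    _group("Heart failure", "I50"),
    _group("Cerebrovascular diseases", "I60-I69"),
    _group("Other diseases of the circulatory system",
           "I00-I09", "I26-I49", "I51", "I52", "I70-I99"),
    _group("Malignant neoplasms", "C00-C97"),
    _group("Alzheimer's and dementia", "G30", "G31", "F01", "F03"),
    _group("Diabetes", "E10-E14"),
    _group("Renal failure", "N17-N19"),
    _group("Sepsis", "A40-A41"),
    _group("Urinary tract infections", "N39"),
    # R09.2 is carved out: it belongs to the respiratory group above
    _group("Undetermined deaths", "R00-R091", "R093-R99"),
)

SELECTED = "Selected causes"
NATURAL = "Natural causes"

#: external-cause exclusion for the "natural" aggregate.  "printed" follows
#: the study's published definition (T00-Y99); "conventional" uses the
#: standard ICD-10 external-cause chapter (V01-Y98).
EXTERNAL_RANGES = {
    "printed": ("T00", "Y99"),
    "conventional": ("V01", "Y98"),
}

#: COVID-19 underlying causes are kept out of the "selected" aggregate.
COVID_CODES = frozenset({"B342", "U071"})


def classify_icd(code: str, groups: tuple[CauseGroupDef, ...] = CAUSE_GROUPS,
                 external_range: str = "printed",
                 covid_excluded: frozenset[str] = COVID_CODES) -> set[str]:
    """Return every cause-group label the code belongs to, including the
    'selected' and 'natural' aggregates."""
    c = normalize_icd(code)
    labels = {g.name for g in groups if g.matches(c)}
    if labels and c not in covid_excluded:
        labels.add(SELECTED)
    lo, hi = EXTERNAL_RANGES[external_range]
    if not (c >= lo and c[: len(hi)] <= hi):
        labels.add(NATURAL)
    return labels


# ---------------------------------------------------------------------------
# series construction
# ---------------------------------------------------------------------------

@dataclass
class CauseSeries:
    """Daily death counts for one cause group and age band, with the summary
    statistics that drive modeling eligibility and likelihood choice."""

    cause: str
    age_group: str
    daily_counts: pd.Series
    total: int = field(init=False)
    mean: float = field(init=False)
    median: float = field(init=False)
    variance: float = field(init=False)
    var_mean_ratio: float = field(init=False)
    pct_zero: float = field(init=False)
    eligible: bool = field(init=False)
    likelihood: str | None = field(init=False)

    def __post_init__(self) -> None:
        y = self.daily_counts.to_numpy()
        self.total = int(y.sum())
        self.mean = float(y.mean())
        self.median = float(np.median(y))
        self.variance = float(y.var(ddof=1)) if len(y) > 1 else 0.0
        self.var_mean_ratio = self.variance / self.mean if self.mean > 0 else float("nan")
        self.pct_zero = float((y == 0).mean() * 100.0)
        self.eligible = eligibility(self.median, self.pct_zero)
        self.likelihood = choose_likelihood(self.var_mean_ratio) if self.eligible else None


def eligibility(median: float, pct_zero: float) -> bool:
    """A series is modelable only if its daily median exceeds 1 and at most
    20 % of days are zero-count."""
    return median > 1 and pct_zero <= 20.0


def choose_likelihood(var_mean_ratio: float) -> str:
    """Quasipoisson for overdispersed series (variance/mean strictly above
    1.6), plain Poisson otherwise."""
    return "quasipoisson" if var_mean_ratio > 1.6 else "poisson"


def read_deaths_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"date", "icd10", "age"} - set(df.columns)
    if missing:
        raise ValueError(f"deaths CSV missing columns: {sorted(missing)}")
    return df


def _age_band(age: int, cut: int = 65) -> str:
    return f"{cut}+" if age >= cut else f"0-{cut - 1}"


def build_series(records: pd.DataFrame, start, end, age_cut: int = 65,
                 groups: tuple[CauseGroupDef, ...] = CAUSE_GROUPS,
                 external_range: str = "printed") -> dict[tuple[str, str], CauseSeries]:
    """Build zero-filled daily series for every (cause group x age band).

    ``records`` needs columns date, icd10, age.  Returns a dict keyed by
    (cause label, age band); every label gets a series even if no death
    matched it (all zeros, pct_zero 100).
    """
    window = pd.date_range(start, end, freq="D")
    bands = [_age_band(0, age_cut), _age_band(age_cut, age_cut)]
    labels = [g.name for g in groups] + [SELECTED, NATURAL]
    counts = {(lab, b): pd.Series(0, index=window, dtype=int) for lab in labels for b in bands}

    if len(records):
        df = pd.DataFrame({
            "date": pd.to_datetime(records["date"]).dt.normalize(),
            "code": records["icd10"].astype(str),
            "band": [_age_band(int(a), age_cut) for a in records["age"]],
        })
        df = df[(df["date"] >= window[0]) & (df["date"] <= window[-1])]
        label_map = {c: sorted(classify_icd(c, groups, external_range=external_range))
                     for c in df["code"].unique()}
        df = df.assign(label=df["code"].map(label_map)).explode("label").dropna(subset=["label"])
        tallied = df.groupby(["label", "band", "date"]).size()
        for (lab, band), sub in tallied.groupby(level=[0, 1]):
            daily = sub.droplevel([0, 1])
            counts[(lab, band)] = counts[(lab, band)].add(daily, fill_value=0).astype(int)

    return {key: CauseSeries(cause=key[0], age_group=key[1], daily_counts=s)
            for key, s in counts.items()}


def summary_table(series: dict[tuple[str, str], CauseSeries]) -> pd.DataFrame:
    """Summary metrics per cause and age band, one row per series."""
    rows = []
    for (cause, band), s in sorted(series.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        rows.append({
            "cause": cause, "age_group": band, "total": s.total,
            "mean": round(s.mean, 2), "median": s.median,
            "variance": round(s.variance, 2),
            "var_mean_ratio": round(s.var_mean_ratio, 2) if np.isfinite(s.var_mean_ratio) else np.nan,
            "pct_zero": round(s.pct_zero, 2),
            "eligible": s.eligible, "likelihood": s.likelihood or "",
        })
    return pd.DataFrame(rows)
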