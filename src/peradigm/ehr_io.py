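"""Reading and validation of EHR, dictionary, covariate and kinship inputs.

Defines the longitudinal patient history container, disease-cohort
construction from ICD-10 case codes, and cohort-wide code frequencies
(the prevalence r_k feeding information content).

ICD-10 dialect: codes are normalized by uppercasing and stripping dots and
whitespace, so ``"Q61.2"`` and ``"q612"`` both become ``"Q612"``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PatientHistory",
    "Cohort",
    "CodeFrequencyTable",
    "normalize_code",
    "read_ehr_long",
    "read_dictionary",
    "read_covariates",
    "read_kinship",
    "define_cohort",
    "code_frequency",
    "filter_confounder",
]


def normalize_code(code: str) -> str:
    """Normalize an ICD-10 code to the dotless uppercase dialect."""
    return str(code).strip().upper().replace(".", "")


@dataclass
class PatientHistory:
    """One individual's ordered longitudinal ICD-10 record.

    ``events`` is sorted non-decreasing by date; duplicate (date, code)
    pairs are allowed — longitudinal repeats are meaningful for the
    repeat-weighted group-embedding variant.
    """

    individual_id: str
    events: list[tuple[date, str]] = field(default_factory=list)

    def codes(self) -> list[str]:
        """Codes in chronological order (repeats kept)."""
        return [c for _, c in self.events]

    def distinct_codes(self) -> set[str]:
        return {c for _, c in self.events}

    def sort(self) -> None:
        """Sort events by date, ties broken by code lexicographic order."""
        self.events.sort(key=lambda e: (e[0], e[1]))


@dataclass
class Cohort:
    """Disease cohort partition: cases vs. background, plus defining codes."""

    case_ids: set[str]
    background_ids: set[str]
    case_codes: set[str]

    def __post_init__(self) -> None:
        overlap = self.case_ids & self.background_ids
        if overlap:
            raise ValueError(f"cases and background overlap: {sorted(overlap)[:5]}")

    @property
    def all_ids(self) -> set[str]:
        return self.case_ids | self.background_ids

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)


@dataclass
class CodeFrequencyTable:
    """Per-code prevalence r_k: proportion of cohort individuals with >=1 record."""

    freq: dict[str, float]
    n_individuals: int

    def __getitem__(self, code: str) -> float:
        return self.freq[code]

    def __contains__(self, code: str) -> bool:
        return code in self.freq

    def get(self, code: str, default: float | None = None) -> float | None:
        return self.freq.get(code, default)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"code": list(self.freq), "r_k": list(self.freq.values())}
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, sniffing tab vs. comma; gzip-transparent."""
    with _open_text(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype=str)


_EHR_ALIASES = {
    "eid": "eid",
    "individual_id": "eid",
    "id": "eid",
    "date": "date",
    "icd10": "code",
    "code": "code",
    "icd": "code",
}


def read_ehr_long(path: str | Path) -> dict[str, PatientHistory]:
    """Read a long-format EHR table (``eid, date, icd10``) into histories.

    Returns one :class:`PatientHistory` per distinct individual, events
    sorted by date (ties by code); row count is conserved. Unparseable
    dates raise with the offending row number.
    """
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    rename = {}
    for low, orig in cols.items():
        if low in _EHR_ALIASES:
            rename[orig] = _EHR_ALIASES[low]
    df = df.rename(columns=rename)
    missing = {"eid", "date", "code"} - set(df.columns)
    if missing:
        raise ValueError(
            f"unknown EHR columns {list(df.columns)}; need eid, date, icd10"
        )
    if df.empty:
        logger.warning("EHR file %s contains no rows", path)
        return {}
    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = parsed.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, after header
        raise ValueError(f"unparseable date {df['date'][bad.idxmax()]!r} at row {row}")
    df["date"] = parsed.dt.date
    df["code"] = df["code"].map(normalize_code)
    histories: dict[str, PatientHistory] = {}
    for eid, sub in df.groupby("eid", sort=True):
        h = PatientHistory(str(eid), list(zip(sub["date"], sub["code"])))
        h.sort()
        histories[str(eid)] = h
    return histories


def read_dictionary(path: str | Path) -> dict[str, str]:
    """Read an ICD-10 ``code, description`` table into a normalized mapping."""
    df = _read_table(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "code" not in cols or "description" not in cols:
        raise ValueError("dictionary needs columns: code, description")
    out: dict[str, str] = {}
    for code, desc in zip(df["code"], df["description"]):
        desc = "" if pd.isna(desc) else str(desc).strip()
        if not desc:
            raise ValueError(f"empty description for code {code!r}")
        out[normalize_code(code)] = desc
    return out


_SEX_MAP = {"0": 0, "1": 1, "f": 0, "m": 1, "female": 0, "male": 1}


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read ``eid, age, sex`` covariates; sex coded 0/1; one row per individual.

    Rows with missing sex are dropped with a warning (mirrors the
    missing-sex sample-removal QC step).
    """
    df = _read_table(path)
    df.columns = [c.lower() for c in df.columns]
    missing = {"eid", "age", "sex"} - set(df.columns)
    if missing:
        raise ValueError(f"covariates missing columns: {sorted(missing)}")
    df["eid"] = df["eid"].astype(str)
    if df["eid"].duplicated().any():
        raise ValueError("duplicate individual ids in covariates")
    df["age"] = pd.to_numeric(df["age"])
    if (df["age"] < 0).any():
        raise ValueError("negative age in covariates")
    sex = df["sex"].astype(str).str.strip().str.lower().map(_SEX_MAP)
    n_miss = int(sex.isna().sum())
    if n_miss:
        logger.warning("dropping %d individuals with missing sex", n_miss)
    df["sex"] = sex
    df = df.dropna(subset=["sex"])
    df["sex"] = df["sex"].astype(int)
    return df.set_index("eid")[["age", "sex"]]


def read_kinship(path: str | Path, threshold: float = 0.0442) -> list[tuple[str, str]]:
    """Read ``id1, id2, kinship`` pairs; keep pairs at/above ``threshold``.

    The default 0.0442 is the conventional KING cutoff separating
    second-degree from third-degree relationships.
    """
    df = _read_table(path)
    df.columns = [c.lower() for c in df.columns]
    if not {"id1", "id2"} <= set(df.columns):
        raise ValueError("kinship table needs columns id1, id2[, kinship]")
    if "kinship" in df.columns:
        kin = pd.to_numeric(df["kinship"])
        df = df[kin >= threshold]
    return [(str(a), str(b)) for a, b in zip(df["id1"], df["id2"])]


def define_cohort(
    histories: Mapping[str, PatientHistory], case_codes: Iterable[str]
) -> Cohort:
    """Cases = individuals with >=1 event of any disease-defining code."""
    case_codes = {normalize_code(c) for c in case_codes}
    if not case_codes:
        raise ValueError("case_codes must be non-empty")
    cases = {
        eid for eid, h in histories.items() if h.distinct_codes() & case_codes
    }
    if not cases:
        raise ValueError("no cases found for the given case codes")
    background = set(histories) - cases
    return Cohort(case_ids=cases, background_ids=background, case_codes=case_codes)


def code_frequency(histories: Mapping[str, PatientHistory]) -> CodeFrequencyTable:
    """Prevalence r_k of each code over the analysis cohort.

    Repeats within an individual count once; the denominator is the full
    cohort, including individuals with no events.
    """
    n = len(histories)
    if n == 0:
        raise ValueError("need at least one individual")
    counts: dict[str, int] = {}
    for h in histories.values():
        for c in h.distinct_codes():
            counts[c] = counts.get(c, 0) + 1
    return CodeFrequencyTable({c: k / n for c, k in counts.items()}, n)


def filter_confounder(
    cohort: Cohort,
    histories: Mapping[str, PatientHistory],
    confounder_codes: Iterable[str],
) -> Cohort:
    """Remove background individuals carrying a confounder code; cases stay.

    Used, e.g., to drop chronic-kidney-disease (N18) individuals without an
    ADPKD diagnosis from the comparison background.
    """
    conf = {normalize_code(c) for c in confounder_codes}
    removed = {
        eid
        for eid in cohort.background_ids
        if eid in histories and histories[eid].distinct_codes() & conf
    }
    if removed:
        logger.info("filter_confounder removed %d background individuals", len(removed))
    return Cohort(
        case_ids=set(cohort.case_ids),
        background_ids=cohort.background_ids - removed,
        case_codes=set(cohort.case_codes),
    )
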