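"""TNM parsing, AJCC 8th-edition medullary-thyroid-carcinoma staging, and
cohort demographic summaries.

Staging here covers MTC only.  MTC staging in AJCC 8 is age-independent
(unlike differentiated thyroid carcinoma): distant metastasis (M1) is stage
IVC; T4b is IVB; T4a or lateral nodal disease (N1b) is IVA; central nodal
disease (N1a) with T1-T3 is III; node-negative disease is I (T1) or II
(T2/T3).  Records with unassessable categories follow the cohort's
missing-data conventions: NX and MX are treated as N0 and M0, and an
unspecified N1 is treated as N1a.

The validation cohort's 21-case MTC clinical table ships with the package
(``data/table1_validation_mtc.tsv``) so every clinical computation runs
without external data.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

T_TOKENS = ("T1a", "T1b", "T1", "T2", "T3a", "T3b", "T3", "T4a", "T4b", "TX")
N_TOKENS = ("N0", "N1a", "N1b", "N1", "NX")
M_TOKENS = ("M0", "M1", "MX")

# longest-first alternation so T1b is not consumed as T1 + trailing junk
_TNM_RE = re.compile(
    r"^(T1A|T1B|T3A|T3B|T4A|T4B|T1|T2|T3|TX)"
    r"(N1A|N1B|N0|N1|NX)"
    r"(M0|M1|MX)$"
)

STAGES = ("I", "II", "III", "IVA", "IVB", "IVC", "NA")


@dataclass(frozen=True)
class TNMRecord:
    t: str | None
    n: str | None
    m: str | None

    @property
    def missing(self) -> bool:
        return self.t is None


def _canonical(token: str) -> str:
    token = token.upper()
    if token in ("TX", "NX", "MX"):
        return token
    if token[-1] in "AB":
        return token[:-1] + token[-1].lower()
    return token


def parse_tnm(text: str) -> TNMRecord:
    """Parse a compact TNM string such as ``T1bNXMX`` (case-insensitive).

    The missing marker ``NA`` (or empty) yields a missing record; any
    unrecognized fragment raises naming the offending text.
    """
    if text is None or pd.isna(text):
        return TNMRecord(None, None, None)
    s = str(text).strip()
    if s == "" or s.upper() in ("NA", "NAN"):
        return TNMRecord(None, None, None)
    m = _TNM_RE.match(s.upper().replace(" ", ""))
    if not m:
        raise ValueError(f"unrecognized TNM fragment in {text!r}")
    t, n, mm = (_canonical(tok) for tok in m.groups())
    return TNMRecord(t=t, n=n, m=mm)


def ajcc8_mtc_stage(rec: TNMRecord) -> str:
    """AJCC 8th-edition MTC stage under the missing-data substitutions
    NX -> N0, MX -> M0, unspecified N1 -> N1a.

    Returns "NA" for a missing record or when the primary tumor is TX with
    otherwise node-negative M0 disease (stage I vs II undeterminable).
    """
    if rec.missing:
        return "NA"
    t, n, m = rec.t, rec.n, rec.m
    if m == "MX":
        m = "M0"
    if n == "NX":
        n = "N0"
    if n == "N1":
        n = "N1a"
    if m == "M1":
        return "IVC"
    if t == "T4b":
        return "IVB"
    if t == "T4a" or n == "N1b":
        return "IVA"
    if n == "N1a":
        return "III" if t != "TX" else "NA"
    # N0, M0
    if t == "TX":
        return "NA"
    return "I" if t in ("T1", "T1a", "T1b") else "II"


def load_validation_mtc_table() -> pd.DataFrame:
    """The packaged 21-case validation MTC clinical table."""
    with resources.files("mtcseq.data").joinpath(
            "table1_validation_mtc.tsv").open() as fh:
        return read_clinical(fh)


def read_clinical(path_or_buffer) -> pd.DataFrame:
    """Read a clinical TSV (sample, age, sex, location, size_cm, bethesda,
    calcitonin_ng_l, tnm) with ``NA`` as the missing marker."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype={"tnm": "string"},
                     na_values=["NA"], keep_default_na=True)
    required = {"sample", "age", "sex", "location", "size_cm", "bethesda",
                "calcitonin_ng_l", "tnm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (df["age"] < 18).any():
        raise ValueError("cohort restricted to patients 18 years and older")
    if (df["calcitonin_ng_l"].dropna() <= 0).any():
        raise ValueError("calcitonin must be positive when present")
    return df


def _pct(count: int, denom: int) -> int:
    """Integer percent, half-up (matching clinical-table presentation)."""
    return int(math.floor(100.0 * count / denom + 0.5))


def summarize_cohort(records: pd.DataFrame) -> dict:
    """Table-style cohort summary: median (range) for numeric columns,
    integer percents per level for categoricals, AJCC-8 stage distribution.

    Missing values are excluded column-wise (each percentage's denominator
    is that column's non-missing count).  For nodule size both the median
    and the mean are reported.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    out: dict = {"n": int(len(records))}

    def med_range(col):
        v = records[col].dropna().astype(float)
        return {"median": float(np.median(v)), "min": float(v.min()),
                "max": float(v.max()), "n": int(len(v))}

    out["age"] = med_range("age")
    out["size_cm"] = med_range("size_cm")
    out["size_cm"]["mean"] = float(records["size_cm"].dropna().mean())
    out["calcitonin_ng_l"] = med_range("calcitonin_ng_l")

    for col in ("sex", "location", "bethesda"):
        v = records[col].dropna()
        out[col] = {lvl: _pct(int((v == lvl).sum()), len(v))
                    for lvl in sorted(v.unique())}

    stages = [ajcc8_mtc_stage(parse_tnm(t)) for t in records["tnm"]]
    evaluable = [s for s in stages if s != "NA"]
    out["stage"] = {s: _pct(evaluable.count(s), len(evaluable))
                    for s in STAGES[:-1] if s in evaluable}
    out["stage_evaluable_n"] = len(evaluable)
    return out
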