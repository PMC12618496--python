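"""Cohort table IO, covariate discretization, and prompt serialization.

A :class:`PatientRecord` carries every covariate as either a legal category
or an explicit ``None`` (missing) — values are never silently defaulted.
Missing cells are written as the literal string ``NA``.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = None

CATEGORIES: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "who_grade": ("2", "3", "4"),
    "histology": ("glioblastoma", "astrocytoma", "oligodendroglioma"),
    "idh": ("wildtype", "mutated"),
    "codeletion_1p19q": ("non-codeleted", "codeleted"),
    "mgmtp": ("unmethylated", "methylated"),
    "eor": ("gross total", "subtotal", "biopsy"),
    "radiotherapy": ("received", "not received"),
    "chemotherapy": ("received", "not received"),
}

TREATMENT_VARIABLES = ("eor", "radiotherapy", "chemotherapy")

# long-form table aliases accepted case-insensitively on read
_CATEGORY_ALIASES = {
    "histology": {
        "glioblastoma, idh wildtype": "glioblastoma",
        "glioblastoma idh-wt": "glioblastoma",
        "astrocytoma, idh-mutant": "astrocytoma",
        "astrocytoma idh-mut": "astrocytoma",
        "oligodendroglioma, idh-mutant, and 1p/19q-codeleted": "oligodendroglioma",
        "oligodendroglioma idh-mut 1p/19q-codel": "oligodendroglioma",
    },
}

COLUMNS = (
    "subject_id", "age", "sex", "kps", "who_grade", "histology", "idh",
    "codeletion_1p19q", "mgmtp", "eor", "radiotherapy", "chemotherapy",
    "os_months", "event", "volume_ref",
)


@dataclass(frozen=True)
class PatientRecord:
    subject_id: str
    os_months: float
    event: int
    age: float | None = None
    sex: str | None = None
    kps: int | None = None
    who_grade: str | None = None
    histology: str | None = None
    idh: str | None = None
    codeletion_1p19q: str | None = None
    mgmtp: str | None = None
    eor: str | None = None
    radiotherapy: str | None = None
    chemotherapy: str | None = None
    volume_ref: str | None = None
    age_bin: str | None = None
    kps_bin: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.os_months) or self.os_months <= 0:
            raise ValueError(
                f"subject {self.subject_id!r}: os_months must be positive, "
                f"got {self.os_months!r}"
            )
        if self.event not in (0, 1):
            raise ValueError(
                f"subject {self.subject_id!r}: event must be 0 or 1, got {self.event!r}"
            )
        for var, legal in CATEGORIES.items():
            val = getattr(self, var)
            if val is not None and val not in legal:
                raise ValueError(
                    f"subject {self.subject_id!r}: illegal {var} value {val!r} "
                    f"(legal: {legal})"
                )
        if self.kps is not None:
            if self.kps % 10 != 0 or not (30 <= self.kps <= 100):
                raise ValueError(
                    f"subject {self.subject_id!r}: KPS must be a multiple of 10 "
                    f"in 30..100, got {self.kps!r}"
                )


@dataclass(frozen=True)
class PromptSet:
    """Ordered (variable, prompt-or-None, modality_tag) triples."""

    entries: tuple[tuple[str, str | None, str], ...]

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for v, _, _ in self.entries)

    def observed(self) -> list[tuple[str, str, str]]:
        return [(v, p, m) for v, p, m in self.entries if p is not None]


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def _parse_cell(var: str, raw, subject_id: str):
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.upper() == "NA":
        return None
    if var == "age":
        return float(s)
    if var == "kps":
        return int(float(s))
    if var == "who_grade":
        s = s.lower().removeprefix("grade").strip()
        return str(int(float(s)))
    s_low = s.lower()
    aliases = _CATEGORY_ALIASES.get(var, {})
    if s_low in aliases:
        return aliases[s_low]
    for legal in CATEGORIES.get(var, ()):
        if s_low == legal:
            return legal
    # histology shorthand: match on leading word
    if var == "histology":
        for legal in CATEGORIES[var]:
            if s_low.startswith(legal):
                return legal
    raise ValueError(f"subject {subject_id!r}: illegal {var} value {s!r}")


def read_cohort(table_path) -> list[PatientRecord]:
    """Read a TSV/CSV cohort table (delimiter autodetected) into validated
    records.  Unknown columns are ignored with a warning."""
    df = pd.read_csv(
        table_path, sep=None, engine="python", dtype=str,
        keep_default_na=False, na_values=[],
    )
    unknown = [c for c in df.columns if c.lower() not in COLUMNS]
    if unknown:
        log.warning("ignoring unknown columns: %s", unknown)
    df.columns = [c.lower() for c in df.columns]
    required = {"subject_id", "os_months", "event"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"cohort table missing required columns: {sorted(missing_cols)}")
    records = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        try:
            os_months = float(row["os_months"])
        except ValueError as exc:
            raise ValueError(
                f"subject {sid!r}: os_months is not numeric: {row['os_months']!r}"
            ) from exc
        kwargs = {"subject_id": sid, "os_months": os_months,
                  "event": int(float(row["event"]))}
        for var in COLUMNS:
            if var in ("subject_id", "os_months", "event") or var not in df.columns:
                continue
            if var == "volume_ref":
                v = str(row[var]).strip()
                kwargs[var] = v if v and v.upper() != "NA" else None
            else:
                kwargs[var] = _parse_cell(var, row[var], sid)
        records.append(PatientRecord(**kwargs))
    return records


def write_cohort(records: list[PatientRecord], table_path) -> None:
    """Write records as a delimited table; missing cells become ``NA``."""
    path = Path(table_path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    for r in records:
        row = {}
        for col in COLUMNS:
            v = getattr(r, col)
            row[col] = "NA" if v is None else v
        rows.append(row)
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(record: PatientRecord) -> PatientRecord:
    """Map age to {<=47, 48-63, >=64} and KPS to {<=50, 60-70, >=80};
    missing propagates to missing.  Boundary values 47/63 and 50/70 belong
    to the lower/middle bins respectively."""
    age_bin = None
    if record.age is not None:
        if record.age <= 47:
            age_bin = "<=47"
        elif record.age <= 63:
            age_bin = "48-63"
        else:
            age_bin = ">=64"
    kps_bin = None
    if record.kps is not None:
        if record.kps <= 50:
            kps_bin = "<=50"
        elif record.kps <= 70:
            kps_bin = "60-70"
        else:
            kps_bin = ">=80"
    return replace(record, age_bin=age_bin, kps_bin=kps_bin)


# ---------------------------------------------------------------------------
# Prompt serialization
# ---------------------------------------------------------------------------

PROMPT_VARIABLES = (
    "age_bin", "sex", "kps_bin", "who_grade", "histology", "idh",
    "codeletion_1p19q", "mgmtp", "eor", "radiotherapy", "chemotherapy",
)


def _load_templates() -> dict[tuple[str, str], tuple[str, str]]:
    with resources.files("mmsurv.data").joinpath("prompt_templates.csv").open() as fh:
        df = pd.read_csv(fh)
    return {
        (row.variable, str(row.category)): (row.prompt, row.modality)
        for row in df.itertuples()
    }


_TEMPLATES: dict[tuple[str, str], tuple[str, str]] | None = None


def _templates() -> dict[tuple[str, str], tuple[str, str]]:
    global _TEMPLATES
    if _TEMPLATES is None:
        _TEMPLATES = _load_templates()
    return _TEMPLATES


def template_table_hash() -> str:
    """Stable digest of the template table; checkpoints embed it so a model
    refuses to load under a different serialization."""
    items = sorted((f"{k[0]}|{k[1]}|{v[0]}|{v[1]}") for k, v in _templates().items())
    return hashlib.sha256("\n".join(items).encode()).hexdigest()


def to_prompts(record: PatientRecord, variables=PROMPT_VARIABLES) -> PromptSet:
    """Render each non-missing variable through the fixed template table.

    Deterministic; treatment variables (EOR, radiotherapy, chemotherapy)
    carry the ``treatment`` modality tag, all others ``clinical_genetic``.
    """
    templates = _templates()
    entries = []
    for var in variables:
        val = getattr(record, var)
        base_var = var
        tag = "treatment" if base_var.replace("_bin", "") in TREATMENT_VARIABLES else "clinical_genetic"
        if val is None:
            entries.append((var, None, tag))
            continue
        key = (var, str(val))
        if key not in templates:
            raise KeyError(f"no prompt template for {key}")
        prompt, modality = templates[key]
        entries.append((var, prompt, modality))
    return PromptSet(tuple(entries))
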