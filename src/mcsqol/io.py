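"""Readers and writers for the cohort tables and result bundles.

Inputs are plain TSV (the assay panel is star-allele/deletion based, so
VCF-style locus resolution does not apply):

* genotype table — columns ``patient_id, gene, variant_id, genotype``;
  genotype is an allele pair ``A/B`` or ``present``/``null`` for the
  deletion assays;
* anamnestic table — ``patient_id, age, gender`` plus the four binary
  event columns; accepts 0/1, yes/no or male/female spellings;
* questionnaire table — ``patient_id, item_index, polarity, answer``.

Outputs are CSV (regression, Pareto, profile, frequency tables) plus a
machine-readable JSON summary, written atomically (nothing is left
behind on failure).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import IO

import pandas as pd

from .genotypes import GenotypeCall
from .qod import Polarity, Answer, QODResponseSheet
from .registry import AssayKind, PolymorphismDef, default_registry, resolve_variant_id

GENOTYPE_COLUMNS = ("patient_id", "gene", "variant_id", "genotype")
ANAMNESTIC_COLUMNS = ("patient_id", "age", "gender", "compounds_exposure",
                      "psychological_trauma", "physical_trauma", "previous_surgery")
QOD_COLUMNS = ("patient_id", "item_index", "polarity", "answer")

_BINARY_CODES = {"0": 0, "1": 1, "no": 0, "yes": 1, "absent": 0, "present": 1}
_GENDER_CODES = {"0": 0, "1": 1, "male": 0, "female": 1, "m": 0, "f": 1}


def _read_tsv(source: str | Path | IO, required: tuple[str, ...]) -> pd.DataFrame:
    # keep_default_na=False: the deletion genotype literal "null" must
    # survive parsing as a string
    df = pd.read_csv(source, sep="\t", dtype=str,
                     keep_default_na=False).rename(columns=str.strip)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing}")
    return df


def read_genotype_table(
    source: str | Path | IO,
    registry: dict[str, PolymorphismDef] | None = None,
) -> list[GenotypeCall]:
    """Parse and validate a genotype TSV into :class:`GenotypeCall` records.

    Every row is checked against the registry (variant known, alleles in
    the allele set, no duplicate patient/variant pair); allele pairs are
    stored in a normalized (lexicographic) order.
    """
    registry = registry if registry is not None else default_registry()
    df = _read_tsv(source, GENOTYPE_COLUMNS)
    calls: list[GenotypeCall] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        where = f"row {idx + 2}"  # 1-based, counting the header line
        try:
            vid = resolve_variant_id(str(row["variant_id"]).strip(), registry)
        except KeyError as exc:
            raise ValueError(f"{where}: {exc.args[0]}") from None
        pdef = registry[vid]
        raw = str(row["genotype"]).strip()
        if pdef.assay_kind is AssayKind.DELETION_PRESENCE:
            alleles: tuple[str, ...] = (raw,)
        else:
            parts = tuple(p.strip() for p in raw.split("/"))
            if len(parts) != 2:
                raise ValueError(
                    f"{where}: genotype {raw!r} for {vid} is not an allele pair")
            alleles = tuple(sorted(parts))
        call = GenotypeCall(str(row["patient_id"]).strip(), vid, alleles)
        try:
            call.validate(pdef)
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from None
        key = (call.patient_id, vid)
        if key in seen:
            raise ValueError(f"{where}: duplicate genotype for patient "
                             f"{call.patient_id}, variant {vid}")
        seen.add(key)
        calls.append(call)
    return calls


def read_anamnestic_table(source: str | Path | IO) -> pd.DataFrame:
    """Parse the anamnestic/demographic TSV into numeric coding.

    Gender is coded 0 = male / 1 = female; the four event columns
    0 = absent / 1 = present.  Non-coercible values and non-positive ages
    are hard errors naming the offending row.
    """
    df = _read_tsv(source, ANAMNESTIC_COLUMNS)
    out = pd.DataFrame({"patient_id": df["patient_id"].str.strip()})
    ages, genders = [], []
    events: dict[str, list[int]] = {c: [] for c in ANAMNESTIC_COLUMNS[3:]}
    for idx, row in df.iterrows():
        where = f"row {idx + 2} (patient {row['patient_id']})"
        try:
            age = float(row["age"])
        except (TypeError, ValueError):
            raise ValueError(f"{where}: age {row['age']!r} is not numeric") from None
        if not math.isfinite(age) or age <= 0:
            raise ValueError(f"{where}: age must be > 0, got {row['age']!r}")
        ages.append(age)
        g = str(row["gender"]).strip().lower()
        if g not in _GENDER_CODES:
            raise ValueError(f"{where}: gender {row['gender']!r} not codable "
                             "(use 0/1 or male/female)")
        genders.append(_GENDER_CODES[g])
        for col in events:
            v = str(row[col]).strip().lower()
            if v not in _BINARY_CODES:
                raise ValueError(f"{where}: {col} value {row[col]!r} not codable "
                                 "(use 0/1 or yes/no)")
            events[col].append(_BINARY_CODES[v])
    out["age"] = ages
    out["gender"] = genders
    for col, vals in events.items():
        out[col] = vals
    return out


def read_qod_table(source: str | Path | IO) -> dict[str, QODResponseSheet]:
    """Parse the questionnaire TSV into per-patient response sheets."""
    df = _read_tsv(source, QOD_COLUMNS)
    sheets: dict[str, QODResponseSheet] = {}
    for pid, group in df.groupby("patient_id", sort=True):
        responses = []
        for idx, row in group.iterrows():
            where = f"row {idx + 2} (patient {pid})"
            try:
                item = int(row["item_index"])
                pol = Polarity(str(row["polarity"]).strip())
                ans = Answer(str(row["answer"]).strip())
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{where}: {exc}") from None
            responses.append((item, pol, ans))
        sheet = QODResponseSheet(str(pid), tuple(responses))
        sheet.validate()
        sheets[str(pid)] = sheet
    return sheets


def write_genotype_table(calls: list[GenotypeCall],
                         registry: dict[str, PolymorphismDef],
                         path: str | Path) -> None:
    rows = [{"patient_id": c.patient_id, "gene": registry[c.variant_id].gene,
             "variant_id": c.variant_id, "genotype": "/".join(c.alleles)}
            for c in calls]
    pd.DataFrame(rows, columns=list(GENOTYPE_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def write_results(results: dict, out_dir: str | Path) -> list[Path]:
    """Write a results bundle to ``out_dir``.

    ``results`` maps artifact name → DataFrame (written as
    ``<name>.csv`` with ≥6 significant digits) or → JSON-serialisable
    object (written as ``<name>.json``).  An empty bundle is an error and
    nothing partial is written: all content is rendered in memory first.
    """
    if not results:
        raise ValueError("empty results bundle: nothing to write")
    out_dir = Path(out_dir)
    rendered: list[tuple[Path, str]] = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            rendered.append((out_dir / f"{name}.csv",
                             obj.to_csv(index=False, float_format="%.8g")))
        else:
            rendered.append((out_dir / f"{name}.json",
                             json.dumps(obj, indent=2, default=float)))
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {out_dir} is not writable: {exc}") from None
    written = []
    for path, text in rendered:
        path.write_text(text)
        written.append(path)
    return written
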