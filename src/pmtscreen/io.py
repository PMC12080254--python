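"""Reading, canonicalizing and validating compound rosters and evidence tables.

All screening stages consume the record types defined here.  Structures are
stored as canonical SMILES; a row whose structure fails to parse is rejected
into a side report rather than aborting the load, so a single bad entry in a
multi-study compilation does not kill a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

ORIGINS = ("synthetic", "natural", "undefined")
#: merge precedence when duplicates disagree: anthropogenic wins
_ORIGIN_RANK = {"synthetic": 0, "natural": 1, "undefined": 2}

TOX_FLAGS = ("CMR", "aquatic_tox", "STOT_RE", "endocrine_disruption")

KNOWN_CLASSES = ("PMT", "vPvM", "PMT_and_vPvM", "not_PMT_vPvM")

PH_MIN, PH_MAX = 4.0, 9.0
DEPTH_MIN_CM, DEPTH_MAX_CM = 0.0, 150.0


@dataclass
class CompoundRecord:
    """One chemical: identity, structure and origin label."""

    compound_id: str
    name: str
    smiles: str
    origin: str = "undefined"
    cas: str | None = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS}, got {self.origin!r}")


@dataclass
class PropertyRecord:
    """Experimental evidence for one compound.

    Empty lists signal missing data; toxicity flags are presence-only
    (absence of a flag is not evidence of non-toxicity).
    """

    compound_id: str
    half_lives_freshwater_days: list[float] = field(default_factory=list)
    log_koc_by_ph: list[tuple[float, float]] = field(default_factory=list)
    tox_flags: set[str] = field(default_factory=set)
    evidence_quality: str = "none"  # "experimental" | "none"

    def __post_init__(self) -> None:
        bad = self.tox_flags - set(TOX_FLAGS)
        if bad:
            raise ValueError(f"unknown toxicity flags {bad}")
        if any(h <= 0 for h in self.half_lives_freshwater_days):
            raise ValueError("half-lives must be positive")
        if any(not (PH_MIN <= ph <= PH_MAX) for ph, _ in self.log_koc_by_ph):
            raise ValueError(f"pH outside [{PH_MIN}, {PH_MAX}]")


@dataclass
class ConcentrationRecord:
    """One concentration observation (ng/g dry weight) at a site/depth."""

    compound_id: str
    site_id: str
    latitude: float
    depth_cm: float
    fraction: str  # "EF" | "NER"
    value_ng_per_g_dw: float

    def __post_init__(self) -> None:
        if self.fraction not in ("EF", "NER"):
            raise ValueError(f"fraction must be EF or NER, got {self.fraction!r}")
        if not (DEPTH_MIN_CM <= self.depth_cm <= DEPTH_MAX_CM):
            raise ValueError("depth outside 0-150 cm")
        if not (self.value_ng_per_g_dw >= 0):
            raise ValueError("concentration must be finite and >= 0")


@dataclass
class KnownListEntry:
    match_key: str  # canonical SMILES or CAS
    listed_class: str

    def __post_init__(self) -> None:
        if self.listed_class not in KNOWN_CLASSES:
            raise ValueError(f"listed_class must be one of {KNOWN_CLASSES}")


@dataclass
class RejectEntry:
    row: int
    compound_id: str | None
    reason: str


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES, or None when the structure does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_roster(path: str | Path) -> tuple[list[CompoundRecord], list[RejectEntry]]:
    """Read a compound roster from CSV/TSV (or SDF) into validated records.

    Rows with unparseable structures are returned in the rejects list with a
    reason; a duplicated compound_id raises, because downstream joins key on
    it.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".sdf":
        return _read_roster_sdf(path)
    df = _read_table(path)
    required = {"compound_id", "smiles"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"roster missing columns: {sorted(missing)}")

    records: list[CompoundRecord] = []
    rejects: list[RejectEntry] = []
    seen_ids: set[str] = set()
    for i, row in df.iterrows():
        cid = row["compound_id"].strip()
        if not cid:
            rejects.append(RejectEntry(int(i), None, "empty compound_id"))
            continue
        if cid in seen_ids:
            raise ValueError(f"duplicate compound_id {cid!r} in roster")
        smi = row["smiles"].strip()
        if canonical_smiles(smi) is None:
            rejects.append(RejectEntry(int(i), cid, f"unparseable SMILES {smi!r}"))
            logger.warning("roster row %d (%s): unparseable SMILES %r", i, cid, smi)
            continue
        origin = str(row.get("origin", "")).strip() or "undefined"
        if origin not in ORIGINS:
            rejects.append(RejectEntry(int(i), cid, f"invalid origin {origin!r}"))
            continue
        seen_ids.add(cid)
        cas = str(row.get("cas", "")).strip() or None
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=str(row.get("name", "")).strip() or cid,
                smiles=smi,
                origin=origin,
                cas=cas,
            )
        )
    return records, rejects


def _read_roster_sdf(path: Path) -> tuple[list[CompoundRecord], list[RejectEntry]]:
    records: list[CompoundRecord] = []
    rejects: list[RejectEntry] = []
    seen: set[str] = set()
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            rejects.append(RejectEntry(i, None, "unparseable SDF entry"))
            continue
        props = mol.GetPropsAsDict()
        cid = str(props.get("compound_id", "")).strip()
        if not cid:
            rejects.append(RejectEntry(i, None, "missing compound_id tag"))
            continue
        if cid in seen:
            raise ValueError(f"duplicate compound_id {cid!r} in SDF")
        origin = str(props.get("origin", "")).strip() or "undefined"
        if origin not in ORIGINS:
            rejects.append(RejectEntry(i, cid, f"invalid origin {origin!r}"))
            continue
        seen.add(cid)
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=str(props.get("name", "")).strip() or cid,
                smiles=Chem.MolToSmiles(mol),
                origin=origin,
                cas=str(props.get("cas", "")).strip() or None,
            )
        )
    return records, rejects


def canonicalize_and_dedup(
    records: Iterable[CompoundRecord],
) -> tuple[list[CompoundRecord], list[str]]:
    """Rewrite structures to canonical SMILES and merge structural duplicates.

    The first record of a duplicate group keeps its id and name; origin is
    merged with precedence synthetic > natural > undefined.  Returns the
    deduplicated records plus a human-readable merge log.
    """
    out: list[CompoundRecord] = []
    index: dict[str, int] = {}
    log: list[str] = []
    for rec in records:
        can = canonical_smiles(rec.smiles)
        if can is None:
            raise ValueError(f"{rec.compound_id}: unparseable SMILES {rec.smiles!r}")
        if can in index:
            keep = out[index[can]]
            if _ORIGIN_RANK[rec.origin] < _ORIGIN_RANK[keep.origin]:
                keep.origin = rec.origin
            if keep.cas is None and rec.cas is not None:
                keep.cas = rec.cas
            log.append(
                f"merged {rec.compound_id} into {keep.compound_id} "
                f"(identical structure {can})"
            )
            continue
        index[can] = len(out)
        out.append(
            CompoundRecord(
                compound_id=rec.compound_id,
                name=rec.name,
                smiles=can,
                origin=rec.origin,
                cas=rec.cas,
            )
        )
    return out, log


def write_roster(records: Iterable[CompoundRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "smiles": r.smiles,
                "origin": r.origin,
                "cas": r.cas or "",
            }
            for r in records
        ]
    )
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def read_properties(path: str | Path) -> dict[str, PropertyRecord]:
    """Read the long-format experimental property table.

    Columns: compound_id, property, value, ph with property one of
    half_life_freshwater_d | log_koc | tox_flag.  log Koc rows with pH outside
    4-9 are dropped with a warning (the mobility criterion is defined on that
    range only); negative half-lives are rejected rows.
    """
    df = _read_table(Path(path))
    required = {"compound_id", "property", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"property table missing columns: {sorted(missing)}")

    records: dict[str, PropertyRecord] = {}
    for i, row in df.iterrows():
        cid = row["compound_id"].strip()
        prop = row["property"].strip()
        rec = records.setdefault(
            cid, PropertyRecord(compound_id=cid, evidence_quality="experimental")
        )
        if prop == "half_life_freshwater_d":
            val = float(row["value"])
            if val <= 0:
                logger.warning("row %d (%s): non-positive half-life rejected", i, cid)
                continue
            rec.half_lives_freshwater_days.append(val)
        elif prop == "log_koc":
            ph = float(row.get("ph", "") or "nan")
            if not (PH_MIN <= ph <= PH_MAX):
                logger.warning(
                    "row %d (%s): log Koc at pH %.1f outside [4, 9] dropped", i, cid, ph
                )
                continue
            rec.log_koc_by_ph.append((ph, float(row["value"])))
        elif prop == "tox_flag":
            flag = row["value"].strip()
            if flag not in TOX_FLAGS:
                logger.warning("row %d (%s): unknown toxicity flag %r", i, cid, flag)
                continue
            rec.tox_flags.add(flag)
        else:
            logger.warning("row %d (%s): unknown property %r", i, cid, prop)
    return records


def get_properties(
    table: Mapping[str, PropertyRecord], compound_id: str
) -> PropertyRecord:
    """Property record for a compound; absence means no experimental evidence."""
    if compound_id in table:
        return table[compound_id]
    return PropertyRecord(compound_id=compound_id, evidence_quality="none")


def read_known_list(path: str | Path) -> list[KnownListEntry]:
    """Load the known PMT/vPvM reference list (match_key, listed_class).

    Structure keys are canonicalized at load time.  Conflicting duplicate
    entries for the same key are a load-time error.
    """
    df = _read_table(Path(path))
    missing = {"match_key", "listed_class"} - set(df.columns)
    if missing:
        raise ValueError(f"known list missing columns: {sorted(missing)}")
    entries: dict[str, KnownListEntry] = {}
    for _, row in df.iterrows():
        key = row["match_key"].strip()
        can = canonical_smiles(key)
        if can is not None:
            key = can
        cls = row["listed_class"].strip()
        if key in entries:
            if entries[key].listed_class != cls:
                raise ValueError(
                    f"conflicting known-list entries for {key!r}: "
                    f"{entries[key].listed_class} vs {cls}"
                )
            continue
        entries[key] = KnownListEntry(match_key=key, listed_class=cls)
    return list(entries.values())


def read_concentrations(
    path: str | Path, valid_ids: set[str] | None = None
) -> tuple[list[ConcentrationRecord], list[RejectEntry]]:
    """Read concentration observations; depth outside 0-150 cm is rejected.

    When ``valid_ids`` is given, rows referencing unknown compounds are
    rejected (logged), matching the ingestion-time depth filter.
    """
    df = _read_table(Path(path))
    required = {"compound_id", "site_id", "latitude", "depth_cm", "fraction", "conc_ng_g_dw"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"concentration table missing columns: {sorted(missing)}")
    records: list[ConcentrationRecord] = []
    rejects: list[RejectEntry] = []
    for i, row in df.iterrows():
        cid = row["compound_id"].strip()
        if valid_ids is not None and cid not in valid_ids:
            rejects.append(RejectEntry(int(i), cid, "unknown compound_id"))
            continue
        try:
            rec = ConcentrationRecord(
                compound_id=cid,
                site_id=row["site_id"].strip(),
                latitude=float(row["latitude"]),
                depth_cm=float(row["depth_cm"]),
                fraction=row["fraction"].strip(),
                value_ng_per_g_dw=float(row["conc_ng_g_dw"]),
            )
        except (ValueError, KeyError) as exc:
            rejects.append(RejectEntry(int(i), cid, str(exc)))
            logger.warning("concentration row %d (%s) rejected: %s", i, cid, exc)
            continue
        records.append(rec)
    return records, rejects
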