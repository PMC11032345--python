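"""Curation of raw inhibitor activity tables into per-molecule potency labels.

Raw tables carry one row per measurement (molecule, SMILES, kinase, Ki in nM,
qualifier).  Curation keeps exact Ki values only, collapses replicate
measurements to a geometric mean when they agree to within one order of
magnitude (discarding the pair otherwise), canonicalizes SMILES, and
optionally removes molecules matching type-II signature substructures so the
downstream analysis sees type-I inhibitors only.  pKi = 9 - log10(Ki / nM).
"""

from __future__ import annotations

import csv
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

QUALIFIERS = {"exact", "greater", "less", "approximate"}
_QUALIFIER_ALIASES = {
    "": "exact", "=": "exact", "exact": "exact",
    ">": "greater", ">=": "greater", "greater": "greater",
    "<": "less", "<=": "less", "less": "less",
    "~": "approximate", "approx": "approximate", "approximate": "approximate",
}

#: replicate Ki values must agree within this max/min ratio (one order of magnitude)
MAX_REPLICATE_RATIO = 10.0


class ActivityTableError(ValueError):
    """Malformed activity table (missing columns, empty file)."""


class SmartsError(ValueError):
    """Invalid SMARTS pattern in a signature list."""


@dataclass(frozen=True)
class ActivityRecord:
    """One raw potency measurement."""

    molecule_id: str
    smiles: str
    kinase_id: str
    ki_nM: float
    qualifier: str = "exact"

    def __post_init__(self):
        if not (self.ki_nM > 0) or not math.isfinite(self.ki_nM):
            raise ValueError(f"ki_nM must be positive and finite, got {self.ki_nM}")
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"unknown qualifier {self.qualifier!r}")


@dataclass(frozen=True)
class CuratedInhibitor:
    """One curated molecule-kinase potency label."""

    molecule_id: str
    kinase_id: str
    canonical_smiles: str
    ki_nM: float
    pki: float


@dataclass
class CurationLog:
    """Row/molecule counts dropped at each curation step."""

    invalid_rows: int = 0
    censored_rows: int = 0
    duplicate_rows: int = 0
    discordant_pairs: int = 0
    type2_matches: dict[str, int] = field(default_factory=dict)
    type2_excluded: int = 0


def pki_from_ki(ki_nM: float) -> float:
    """pKi = -log10(Ki in molar) = 9 - log10(Ki in nM)."""
    return 9.0 - math.log10(ki_nM)


def read_activity_table(path, clog: CurationLog | None = None) -> list[ActivityRecord]:
    """Parse a CSV/TSV activity table.

    Required columns: molecule_id, smiles, kinase_id, ki_nM.  The qualifier
    column is optional (default ``exact``; ``>``/``<``/``~`` aliases are
    normalized).  Rows with unparsable SMILES or non-positive Ki are skipped
    and counted.
    """
    path = Path(path)
    clog = clog if clog is not None else CurationLog()
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise ActivityTableError(f"{path}: empty file")
        missing = {"molecule_id", "smiles", "kinase_id", "ki_nM"} - set(reader.fieldnames)
        if missing:
            raise ActivityTableError(f"{path}: missing columns {sorted(missing)}")
        records = []
        for row in reader:
            try:
                ki = float(row["ki_nM"])
            except (TypeError, ValueError):
                clog.invalid_rows += 1
                continue
            qual = _QUALIFIER_ALIASES.get((row.get("qualifier") or "").strip().lower())
            if qual is None or ki <= 0 or not math.isfinite(ki):
                clog.invalid_rows += 1
                continue
            if Chem.MolFromSmiles(row["smiles"]) is None:
                clog.invalid_rows += 1
                continue
            records.append(ActivityRecord(row["molecule_id"], row["smiles"],
                                          row["kinase_id"], ki, qual))
    if not records and clog.invalid_rows == 0:
        raise ActivityTableError(f"{path}: no data rows")
    if clog.invalid_rows:
        log.info("%s: skipped %d invalid rows", path, clog.invalid_rows)
    return records


def drop_censored(records: list[ActivityRecord],
                  clog: CurationLog | None = None) -> list[ActivityRecord]:
    """Keep exact-qualifier measurements only (censored/approximate excluded)."""
    kept = [r for r in records if r.qualifier == "exact"]
    if clog is not None:
        clog.censored_rows += len(records) - len(kept)
    return kept


def _geometric_mean(values) -> float:
    return math.exp(sum(math.log(v) for v in values) / len(values))


def aggregate_potency(records: list[ActivityRecord],
                      clog: CurationLog | None = None) -> CuratedInhibitor | None:
    """Aggregate exact measurements of one molecule-kinase pair.

    Duplicate identical rows are collapsed first.  A single value stands;
    multiple values are combined by geometric mean provided max/min <= 10
    (boundary inclusive), otherwise the pair is discarded (returns None).
    """
    if not records:
        raise ValueError("no records for pair")
    first = records[0]
    if any(r.molecule_id != first.molecule_id or r.kinase_id != first.kinase_id
           for r in records):
        raise ValueError("aggregate_potency expects records of a single molecule-kinase pair")
    values = sorted({r.ki_nM for r in records})
    if clog is not None:
        clog.duplicate_rows += len(records) - len(values)
    if values[-1] / values[0] > MAX_REPLICATE_RATIO:
        if clog is not None:
            clog.discordant_pairs += 1
        return None
    ki = values[0] if len(values) == 1 else _geometric_mean(values)
    mol = Chem.MolFromSmiles(first.smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {first.smiles!r}")
    return CuratedInhibitor(first.molecule_id, first.kinase_id,
                            Chem.MolToSmiles(mol), ki, pki_from_ki(ki))


def read_smarts_list(path) -> list[str]:
    """Read a SMARTS list, one per line, '#' comments allowed."""
    from .aadata import _strip_comment

    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        pat = _strip_comment(line)
        if not pat:
            continue
        if Chem.MolFromSmarts(pat) is None:
            raise SmartsError(f"{path}:{i}: invalid SMARTS {pat!r}")
        out.append(pat)
    return out


def apply_type2_filter(inhibitors: list[CuratedInhibitor], smarts_list: list[str],
                       clog: CurationLog | None = None) -> list[CuratedInhibitor]:
    """Exclude molecules matching any signature substructure.

    An empty pattern list keeps everything.  Per-pattern match counts are
    logged (a molecule matching several patterns counts for each).
    """
    patterns = []
    for s in smarts_list:
        pat = Chem.MolFromSmarts(s)
        if pat is None:
            raise SmartsError(f"invalid SMARTS {s!r}")
        patterns.append((s, pat))
    if not patterns:
        return list(inhibitors)
    counts = {s: 0 for s, _ in patterns}
    kept = []
    for inh in inhibitors:
        mol = Chem.MolFromSmiles(inh.canonical_smiles)
        hit = False
        for s, pat in patterns:
            if mol.HasSubstructMatch(pat):
                counts[s] += 1
                hit = True
        if not hit:
            kept.append(inh)
    if clog is not None:
        for s, c in counts.items():
            clog.type2_matches[s] = clog.type2_matches.get(s, 0) + c
        clog.type2_excluded += len(inhibitors) - len(kept)
    log.info("type-II filter: %d/%d molecules excluded", len(inhibitors) - len(kept),
             len(inhibitors))
    return kept


def curate(records: list[ActivityRecord], smarts_list: list[str] | None = None,
           clog: CurationLog | None = None) -> list[CuratedInhibitor]:
    """Full curation: censoring, aggregation, canonicalization, type-II filter.

    Output has unique (molecule, kinase) keys; the operation is idempotent on
    its own output (re-curating curated data changes nothing).
    """
    clog = clog if clog is not None else CurationLog()
    exact = drop_censored(records, clog)
    by_pair: dict[tuple[str, str], list[ActivityRecord]] = defaultdict(list)
    for r in exact:
        by_pair[(r.molecule_id, r.kinase_id)].append(r)
    curated = []
    for pair_records in by_pair.values():
        agg = aggregate_potency(pair_records, clog)
        if agg is not None:
            curated.append(agg)
    curated.sort(key=lambda c: (c.kinase_id, c.molecule_id))
    if smarts_list:
        curated = apply_type2_filter(curated, smarts_list, clog)
    return curated


def read_curated_csv(path) -> list[CuratedInhibitor]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(CuratedInhibitor(row["molecule_id"], row["kinase_id"],
                                        row["canonical_smiles"], float(row["ki_nM"]),
                                        float(row["pki"])))
    return out


def write_curated_csv(inhibitors: list[CuratedInhibitor], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["molecule_id", "kinase_id", "canonical_smiles", "ki_nM", "pki"])
        for c in inhibitors:
            w.writerow([c.molecule_id, c.kinase_id, c.canonical_smiles,
                        repr(c.ki_nM), repr(c.pki)])
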