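"""Synthetic study generator.

Produces complete studies -- kinase sequences plus per-kinase inhibitor
activity tables with known ground truth -- carrying the statistical
structure the analysis assumes:

* sequences of realistic kinase length (300-1600 residues) with
  class-dependent tripeptide motifs inserted at a configured per-100-residue
  rate (composition signal for the classifiers to find);
* ligand sets built from a bundled library of drug-like scaffold cores
  (>= 10 heavy atoms) decorated with small substituents (<= 5 heavy atoms),
  so same-scaffold molecules form matched molecular pairs by construction;
* planted activity cliffs with an unambiguous potency gap: non-cliff pairs
  differ by <= 1.0 log10 Ki, cliff pairs by >= 2.3, so measurement noise can
  never flip a label across the 2.0 cliff threshold;
* a configurable fraction of decoy molecules carrying a demo type-II
  signature substructure, exercising the SMARTS pre-filter.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from . import aadata
from .aadata import AA_ORDER
from .curation import ActivityRecord
from .descriptors import ProteinSeq
from .mmp import CLASS_HIGH, CLASS_LOW, CLASS_NO

#: potency noise is clipped to +-NOISE_CLIP log units so that planted
#: non-cliff pairs stay <= 1.0 and planted cliffs stay >= 2.3 apart
NOISE_CLIP = 0.35
CLIFF_OFFSET = 3.0

CLASSES = (CLASS_NO, CLASS_LOW, CLASS_HIGH)


class ConfigurationError(ValueError):
    """Invalid study configuration."""


def _default_mixture() -> dict[str, float]:
    # class proportions observed in the bundled 80-kinase survey (36/16/28)
    return {CLASS_NO: 0.45, CLASS_LOW: 0.20, CLASS_HIGH: 0.35}


def _default_tripeptides() -> dict[str, list[tuple[str, float]]]:
    # motifs and the classes they mark, following the survey trends:
    # VME marks cliff-resistant kinases, GTT/EMY the cliff-prone ones
    return {CLASS_NO: [("VME", 0.5)], CLASS_LOW: [], CLASS_HIGH: [("GTT", 0.5), ("EMY", 0.3)]}


def _default_cliff_rates() -> dict[str, float]:
    return {CLASS_NO: 0.0, CLASS_LOW: 0.005, CLASS_HIGH: 0.03}


@dataclass
class StudyConfig:
    """Parameters of a synthetic study; defaults match the study design."""

    n_kinases: int = 80
    class_mixture: dict[str, float] = field(default_factory=_default_mixture)
    seq_length_range: tuple[int, int] = (300, 1600)
    planted_tripeptides: dict[str, list[tuple[str, float]]] = field(
        default_factory=_default_tripeptides)
    n_scaffolds_per_kinase: int = 20
    substituents_per_scaffold: int = 6
    cliff_rate: dict[str, float] = field(default_factory=_default_cliff_rates)
    ki_log10_sd: float = 0.2
    type2_plant_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_kinases < 1:
            raise ConfigurationError("n_kinases must be positive")
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class mixture proportions must sum to 1")
        if set(self.class_mixture) - set(CLASSES):
            raise ConfigurationError(f"unknown classes {set(self.class_mixture) - set(CLASSES)}")
        lo, hi = self.seq_length_range
        if lo <= 35:
            raise ConfigurationError(
                "seq_length_range lower bound must exceed 35 (lag-based descriptors need > 30)")
        if hi < lo:
            raise ConfigurationError("empty seq_length_range")
        for cls, rate in self.cliff_rate.items():
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"cliff_rate[{cls!r}] must be in [0, 1)")
        if not 0.0 <= self.type2_plant_rate < 1.0:
            raise ConfigurationError("type2_plant_rate must be in [0, 1)")
        for cls, entries in self.planted_tripeptides.items():
            for tri, rate in entries:
                if len(tri) != 3 or set(tri) - set(AA_ORDER):
                    raise ConfigurationError(f"invalid tripeptide {tri!r}")
                if not 0.0 <= rate <= 100.0:
                    raise ConfigurationError(f"invalid insertion rate {rate} for {tri!r}")
        if self.n_scaffolds_per_kinase < 1 or self.substituents_per_scaffold < 2:
            raise ConfigurationError("need >= 1 scaffold and >= 2 substituents per scaffold")


@dataclass
class StudyBundle:
    """A generated study: proteins, activity tables and ground truth."""

    config: StudyConfig
    proteins: list[ProteinSeq]
    activity_tables: dict[str, list[ActivityRecord]]
    truth: dict

    def class_of(self, kinase_id: str) -> str:
        return self.truth["kinases"][kinase_id]["class"]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _class_assignment(config: StudyConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic largest-remainder class counts, shuffled order."""
    classes = [c for c in CLASSES if config.class_mixture.get(c, 0) > 0]
    exact = {c: config.class_mixture[c] * config.n_kinases for c in classes}
    counts = {c: int(math.floor(v)) for c, v in exact.items()}
    short = config.n_kinases - sum(counts.values())
    for c in sorted(classes, key=lambda c: exact[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    labels = [c for c in classes for _ in range(counts[c])]
    rng.shuffle(labels)
    return labels


def generate_protein_set(config: StudyConfig) -> tuple[list[ProteinSeq], dict[str, str]]:
    """Sequences with class-dependent planted tripeptides; deterministic by seed.

    Per kinase the background is uniform over the 20 letters; each planted
    motif of its class is *inserted* (not substituted) a Binomial(L, rate/100)
    number of times at uniformly random positions.
    """
    labels = _class_assignment(config, _rng(config.seed, 0))
    lo, hi = config.seq_length_range
    proteins, classes = [], {}
    for i, cls in enumerate(labels):
        kid = f"KIN{i + 1:04d}"
        rng = _rng(config.seed, 1, i)
        length = int(rng.integers(lo, hi + 1))
        seq = list(AA_ORDER[j] for j in rng.integers(0, 20, size=length))
        inserts: list[tuple[int, str]] = []
        for tri, rate in config.planted_tripeptides.get(cls, []):
            k = int(rng.binomial(length, rate / 100.0))
            for pos in rng.integers(0, length + 1, size=k):
                inserts.append((int(pos), tri))
        for pos, tri in sorted(inserts, reverse=True):
            seq[pos:pos] = list(tri)
        proteins.append(ProteinSeq(kid, "".join(seq)))
        classes[kid] = cls
    return proteins, classes


# ---------------------------------------------------------------------------
# molecule assembly

def build_molecule(scaffold: str, substituent: str) -> str:
    """Join a scaffold and substituent at their ``[*:1]`` attachment points."""
    sc = Chem.MolFromSmiles(scaffold)
    sub = Chem.MolFromSmiles(substituent)
    if sc is None or sub is None:
        raise ValueError(f"unparsable fragment {scaffold!r} / {substituent!r}")
    joined = Chem.molzip(Chem.CombineMols(sc, sub))
    joined = Chem.RemoveHs(joined)
    Chem.SanitizeMol(joined)
    return Chem.MolToSmiles(joined)


def _clipped_noise(rng: np.random.Generator, sd: float) -> float:
    return float(np.clip(rng.normal(0.0, sd), -NOISE_CLIP, NOISE_CLIP))


def planted_cliff_count(config: StudyConfig, class_label: str) -> int:
    """Number of 2-molecule cliff groups planted for a kinase of this class."""
    rate = config.cliff_rate.get(class_label, 0.0)
    if rate == 0.0:
        return 0
    k = config.substituents_per_scaffold
    m_regular = config.n_scaffolds_per_kinase * (k * (k - 1) // 2)
    return max(1, round(rate * m_regular / (1.0 - rate)))


def generate_inhibitor_table(config: StudyConfig, kinase_id: str, class_label: str,
                             kinase_index: int = 0) -> tuple[list[ActivityRecord], dict]:
    """One kinase's activity table plus its planted ground truth.

    Regular scaffold groups of ``substituents_per_scaffold`` molecules share a
    base potency (pairwise log10 Ki gap <= 2 * NOISE_CLIP); each planted
    cliff is a dedicated 2-molecule group whose members differ by
    CLIFF_OFFSET +- noise (>= 2.3 log units).  Decoy molecules carrying the
    demo type-II signature are appended so that the configured fraction of
    all molecules matches the signature SMARTS.
    """
    if class_label not in CLASSES:
        raise ConfigurationError(f"unknown class {class_label!r}")
    rng = _rng(config.seed, 2, kinase_index)
    scaffolds = list(aadata.scaffold_library())
    subs = [s for s in aadata.substituent_library()]
    k = config.substituents_per_scaffold
    if k > len(subs):
        raise ConfigurationError(f"substituents_per_scaffold > library size {len(subs)}")
    n_cliff = planted_cliff_count(config, class_label)
    n_scaff = config.n_scaffolds_per_kinase
    if n_scaff + n_cliff > len(scaffolds):
        raise ConfigurationError(
            f"need {n_scaff + n_cliff} scaffolds, library has {len(scaffolds)}")
    chosen = rng.choice(len(scaffolds), size=n_scaff + n_cliff, replace=False)

    records: list[ActivityRecord] = []
    cliff_pairs: list[tuple[str, str]] = []
    serial = itertools.count(1)

    def add(smiles: str, log_ki: float) -> str:
        mid = f"{kinase_id}-M{next(serial):04d}"
        records.append(ActivityRecord(mid, smiles, kinase_id, 10.0 ** log_ki))
        return mid

    for si in chosen[:n_scaff]:
        base = rng.uniform(0.0, 3.0)
        for sub_i in rng.choice(len(subs), size=k, replace=False):
            add(build_molecule(scaffolds[si], subs[sub_i]),
                base + _clipped_noise(rng, config.ki_log10_sd))
    for si in chosen[n_scaff:]:
        base = rng.uniform(0.0, 3.0)
        sub_a, sub_b = rng.choice(len(subs), size=2, replace=False)
        id_lo = add(build_molecule(scaffolds[si], subs[sub_a]),
                    base + _clipped_noise(rng, config.ki_log10_sd))
        id_hi = add(build_molecule(scaffolds[si], subs[sub_b]),
                    base + CLIFF_OFFSET + _clipped_noise(rng, config.ki_log10_sd))
        cliff_pairs.append((id_lo, id_hi))

    n_core = len(records)
    p = config.type2_plant_rate
    n_decoy = round(p * n_core / (1.0 - p)) if p > 0 else 0
    plant = aadata.type2_plant_fragment()
    decoy_ids = []
    if n_decoy:
        decoy_scaffolds = rng.choice(len(scaffolds), size=n_decoy,
                                     replace=n_decoy > len(scaffolds))
        for si in decoy_scaffolds:
            decoy_ids.append(add(build_molecule(scaffolds[si], plant),
                                 rng.uniform(0.0, 3.0)))

    m_regular = n_scaff * (k * (k - 1) // 2)
    planted_pct = 100.0 * n_cliff / (n_cliff + m_regular)
    truth = {
        "class": class_label,
        "cliff_pairs": sorted(map(list, cliff_pairs)),
        "n_mmps_planted": n_cliff + m_regular,
        "planted_pct": planted_pct,
        "type2_molecules": decoy_ids,
    }
    return records, truth


def generate_study(config: StudyConfig) -> StudyBundle:
    """Full study bundle: proteins, activity tables and ground truth."""
    proteins, classes = generate_protein_set(config)
    tables: dict[str, list[ActivityRecord]] = {}
    truth: dict = {"classes_present": sorted(set(classes.values())), "kinases": {}}
    for i, prot in enumerate(proteins):
        records, ktruth = generate_inhibitor_table(config, prot.kinase_id,
                                                   classes[prot.kinase_id], i)
        tables[prot.kinase_id] = records
        truth["kinases"][prot.kinase_id] = ktruth
    truth["planted_tripeptides"] = {
        cls: [[tri, rate] for tri, rate in entries]
        for cls, entries in config.planted_tripeptides.items()
    }
    return StudyBundle(config, proteins, tables, truth)


def write_fixtures(bundle: StudyBundle, outdir) -> dict[str, Path]:
    """Write FASTA + activity CSV + truth JSON + SMARTS fixtures; byte-stable."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    fasta = outdir / "proteins.fasta"
    recs = [SeqRecord(Seq(p.sequence), id=p.kinase_id,
                      description=bundle.class_of(p.kinase_id).replace(" ", "_"))
            for p in bundle.proteins]
    seqio_write(recs, str(fasta), "fasta")
    paths["fasta"] = fasta

    activities = outdir / "activities.csv"
    with open(activities, "w", newline="") as fh:
        fh.write("molecule_id,smiles,kinase_id,ki_nM,qualifier\n")
        for kid in sorted(bundle.activity_tables):
            for r in bundle.activity_tables[kid]:
                fh.write(f"{r.molecule_id},{r.smiles},{r.kinase_id},{r.ki_nM!r},{r.qualifier}\n")
    paths["activities"] = activities

    truth = outdir / "truth.json"
    truth.write_text(json.dumps(bundle.truth, indent=1, sort_keys=True))
    paths["truth"] = truth

    smarts = outdir / "type2_signatures.smarts"
    smarts.write_text("\n".join(aadata.demo_type2_smarts()) + "\n")
    paths["smarts"] = smarts
    return paths
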