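"""Matched-molecular-pair mining, activity-cliff calling and propensity stats.

An MMP is a pair of molecules sharing a core of >= 10 heavy atoms and
differing in a single terminal fragment of <= 5 heavy atoms (attachment
points not counted).  Pairs are found by single-cut fragmentation over
acyclic single bonds, indexing the canonical core strings.  A hydrogen
"fragment" is represented by a bare attachment marker so H -> F style
transforms are expressible.  A pair whose absolute pKi difference is at
least 2 log units (a 100-fold potency ratio) is an activity cliff (AC).

Per-kinase propensity is ACs/MMPs% = 100 * n_acs / n_mmps, classified under
three schemes:

* default: 0 -> "No ACs"; (0, 1] -> "Low ACs"; > 1 -> "High ACs"
* A (binary): 0 -> "No ACs"; > 0 -> "With ACs"
* B: as default with the Low/High boundary at 2.59 (the survey mean + 1 SD)
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, replace
from functools import lru_cache

from rdkit import Chem

from .curation import CuratedInhibitor

MAX_FRAGMENT_HEAVY = 5
MIN_CORE_HEAVY = 10
CLIFF_DELTA_PKI = 2.0
THRESHOLD_B_DEFAULT = 2.59

CLASS_NO = "No ACs"
CLASS_LOW = "Low ACs"
CLASS_HIGH = "High ACs"
CLASS_WITH = "With ACs"
CLASS_ORDER = {"default": (CLASS_NO, CLASS_LOW, CLASS_HIGH),
               "A": (CLASS_NO, CLASS_WITH),
               "B": (CLASS_NO, CLASS_LOW, CLASS_HIGH)}


@lru_cache(maxsize=1)
def hydrogen_fragment() -> str:
    """Canonical string of the bare attachment marker standing for hydrogen."""
    return Chem.MolToSmiles(Chem.MolFromSmiles("[H][*]"))


@dataclass(frozen=True)
class FragmentationCut:
    """One valid single-cut of a molecule into core + small fragment."""

    core: str
    fragment: str
    core_heavy: int
    fragment_heavy: int


@dataclass(frozen=True)
class MatchedMolecularPair:
    mol_a: str
    mol_b: str
    kinase_id: str
    core: str
    frag_a: str
    frag_b: str
    delta_pki: float
    is_cliff: bool = False

    @property
    def transform_key(self) -> tuple[str, str]:
        return tuple(sorted((self.frag_a, self.frag_b)))


@dataclass(frozen=True)
class KinasePropensity:
    kinase_id: str
    n_inhibitors: int
    n_mmps: int
    n_acs: int
    acs_over_mmps_pct: float
    class_default: str
    class_A: str
    class_B: str


@dataclass(frozen=True)
class TransformCrossTab:
    """Shared-transform behavior across the kinases where it occurs (>= 2)."""

    transform_key: tuple[str, str]
    status_by_kinase: tuple[tuple[str, bool], ...]  # kinase -> any cliff pair
    n_ac_kinases: int
    n_nonac_kinases: int
    behavior: str  # exclusive_AC / varying / never_AC


def _as_mol(molecule) -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    mol = Chem.MolFromSmiles(molecule)
    if mol is None:
        raise ValueError(f"unparsable molecule {molecule!r}")
    return mol


def _heavy_count(mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def enumerate_single_cuts(molecule, max_fragment_heavy: int = MAX_FRAGMENT_HEAVY,
                          min_core_heavy: int = MIN_CORE_HEAVY) -> list[FragmentationCut]:
    """All valid single cuts over acyclic single bonds between heavy atoms.

    Each cut splits the molecule in two; the side with <= ``max_fragment_heavy``
    heavy atoms is the fragment, the side with >= ``min_core_heavy`` the core.
    Cuts violating either bound are discarded.  Attachment points are a
    generic ``[*]`` marker and both pieces are canonicalized, so core strings
    are directly comparable.
    """
    mol = _as_mol(molecule)
    total = _heavy_count(mol)
    cuts = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetBeginAtom().GetAtomicNum() <= 1 or bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        frag = Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True,
                                    dummyLabels=[(0, 0)])
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
        if len(pieces) != 2:
            continue
        h0, h1 = (_heavy_count(p) for p in pieces)
        if min(h0, h1) > max_fragment_heavy or max(h0, h1) < min_core_heavy:
            continue
        if h0 >= h1:
            core_mol, frag_mol, core_h, frag_h = pieces[0], pieces[1], h0, h1
        else:
            core_mol, frag_mol, core_h, frag_h = pieces[1], pieces[0], h1, h0
        if frag_h > max_fragment_heavy or core_h < min_core_heavy:
            continue
        assert core_h + frag_h == total
        cuts.append(FragmentationCut(Chem.MolToSmiles(core_mol),
                                     Chem.MolToSmiles(frag_mol), core_h, frag_h))
    return cuts


def enumerate_hydrogen_cuts(molecule, min_core_heavy: int = MIN_CORE_HEAVY) -> list[FragmentationCut]:
    """Virtual cuts replacing one hydrogen by an attachment marker.

    The core is the whole molecule with a ``[*]`` attached at the hydrogen
    position and the fragment is the bare marker (zero heavy atoms).  These
    cuts let an unsubstituted molecule pair with its mono-substituted
    analogs (e.g. an H -> F transform).
    """
    mol = _as_mol(molecule)
    total = _heavy_count(mol)
    if total < min_core_heavy:
        return []
    cores = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1 or atom.GetTotalNumHs() == 0:
            continue
        rw = Chem.RWMol(mol)
        dummy = rw.AddAtom(Chem.Atom(0))
        rw.AddBond(atom.GetIdx(), dummy, Chem.BondType.SINGLE)
        try:
            Chem.SanitizeMol(rw)
        except Exception:
            continue
        cores.add(Chem.MolToSmiles(rw))
    return [FragmentationCut(core, hydrogen_fragment(), total, 0) for core in sorted(cores)]


def find_mmps(inhibitors: list[CuratedInhibitor], kinase_id: str | None = None,
              max_fragment_heavy: int = MAX_FRAGMENT_HEAVY,
              min_core_heavy: int = MIN_CORE_HEAVY) -> list[MatchedMolecularPair]:
    """Find all MMPs among the curated inhibitors of one kinase.

    Cuts (bond cuts plus hydrogen cuts) are indexed by canonical core; two
    molecules sharing a core with different fragments form an MMP.  A pair
    reachable through several distinct shared cores is reported once, through
    the largest core (ties broken lexicographically on the fragment pair).
    The pair's ``delta_pki`` is attached; cliff labelling is separate.
    """
    if kinase_id is None:
        kinase_id = inhibitors[0].kinase_id if inhibitors else ""
    by_core: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
    pki = {}
    for inh in sorted(inhibitors, key=lambda c: c.molecule_id):
        if inh.molecule_id in pki:
            raise ValueError(f"duplicate molecule id {inh.molecule_id!r}")
        pki[inh.molecule_id] = inh.pki
        mol = _as_mol(inh.canonical_smiles)
        cuts = enumerate_single_cuts(mol, max_fragment_heavy, min_core_heavy)
        cuts += enumerate_hydrogen_cuts(mol, min_core_heavy)
        seen = set()
        for cut in cuts:
            key = (cut.core, cut.fragment)
            if key not in seen:  # symmetric molecules can repeat a cut
                seen.add(key)
                by_core[cut.core].append((inh.molecule_id, cut.fragment, cut.core_heavy))
        del mol
    best: dict[tuple[str, str], tuple[int, tuple[str, str], str]] = {}
    for core, entries in by_core.items():
        if len(entries) < 2:
            continue
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                id_a, frag_a, core_h = entries[i]
                id_b, frag_b, _ = entries[j]
                if id_a == id_b or frag_a == frag_b:
                    continue
                if id_a > id_b:
                    id_a, id_b, frag_a, frag_b = id_b, id_a, frag_b, frag_a
                cand = (-core_h, tuple(sorted((frag_a, frag_b))), core, frag_a, frag_b)
                prev = best.get((id_a, id_b))
                if prev is None or cand[:3] < prev[:3]:
                    best[(id_a, id_b)] = cand
    mmps = []
    for (id_a, id_b), (_, _, core, frag_a, frag_b) in sorted(best.items()):
        mmps.append(MatchedMolecularPair(
            id_a, id_b, kinase_id, core, frag_a, frag_b,
            abs(pki[id_a] - pki[id_b])))
    return mmps


def label_cliffs(mmps: list[MatchedMolecularPair],
                 threshold: float = CLIFF_DELTA_PKI) -> list[MatchedMolecularPair]:
    """Set is_cliff = (delta_pKi >= threshold); >= 100-fold is a cliff."""
    return [replace(m, is_cliff=m.delta_pki >= threshold) for m in mmps]


def kinase_propensity(kinase_id: str, mmps: list[MatchedMolecularPair],
                      n_inhibitors: int,
                      threshold_b: float = THRESHOLD_B_DEFAULT) -> KinasePropensity:
    """Per-kinase MMP/AC counts, ACs/MMPs% and class labels under all schemes."""
    n_mmps = len(mmps)
    n_acs = sum(m.is_cliff for m in mmps)
    pct = 100.0 * n_acs / n_mmps if n_mmps else 0.0
    return KinasePropensity(kinase_id, n_inhibitors, n_mmps, n_acs, pct,
                            assign_class(pct, "default"),
                            assign_class(pct, "A"),
                            assign_class(pct, "B", threshold_b))


def propensity_pct(n_mmps: int, n_acs: int) -> float:
    """ACs/MMPs% = 100 * n_acs / n_mmps (0 when there are no MMPs)."""
    return 100.0 * n_acs / n_mmps if n_mmps else 0.0


def assign_class(pct: float, scheme: str = "default",
                 threshold_b: float = THRESHOLD_B_DEFAULT) -> str:
    """Classify an ACs/MMPs% value under a threshold scheme (boundaries inclusive)."""
    if pct < 0:
        raise ValueError("pct must be >= 0")
    if scheme == "default":
        return CLASS_NO if pct == 0 else (CLASS_LOW if pct <= 1.0 else CLASS_HIGH)
    if scheme == "A":
        return CLASS_NO if pct == 0 else CLASS_WITH
    if scheme == "B":
        return CLASS_NO if pct == 0 else (CLASS_LOW if pct <= threshold_b else CLASS_HIGH)
    raise ValueError(f"unknown classification scheme {scheme!r}")


def transform_crosstab(mmps: list[MatchedMolecularPair]) -> list[TransformCrossTab]:
    """Cross-tabulate transforms shared by >= 2 kinases.

    A transform's status in a kinase is AC if any of its pairs there is a
    cliff.  Behavior is ``exclusive_AC`` (AC wherever observed), ``never_AC``
    or ``varying``.
    """
    status: dict[tuple[str, str], dict[str, bool]] = defaultdict(dict)
    for m in mmps:
        k = m.transform_key
        status[k][m.kinase_id] = status[k].get(m.kinase_id, False) or m.is_cliff
    out = []
    for key in sorted(status):
        per_kinase = status[key]
        if len(per_kinase) < 2:
            continue
        n_ac = sum(per_kinase.values())
        n_non = len(per_kinase) - n_ac
        behavior = ("exclusive_AC" if n_non == 0
                    else "never_AC" if n_ac == 0 else "varying")
        out.append(TransformCrossTab(key, tuple(sorted(per_kinase.items())),
                                     n_ac, n_non, behavior))
    return out


def write_mmp_csv(mmps: list[MatchedMolecularPair], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mol_a", "mol_b", "kinase_id", "core", "frag_a", "frag_b",
                    "delta_pki", "is_cliff"])
        for m in mmps:
            w.writerow([m.mol_a, m.mol_b, m.kinase_id, m.core, m.frag_a, m.frag_b,
                        repr(m.delta_pki), int(m.is_cliff)])


def write_propensity_csv(props: list[KinasePropensity], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kinase_id", "n_inhibitors", "n_mmps", "n_acs",
                    "acs_over_mmps_pct", "class_default", "class_A", "class_B"])
        for p in props:
            w.writerow([p.kinase_id, p.n_inhibitors, p.n_mmps, p.n_acs,
                        f"{p.acs_over_mmps_pct:.1f}", p.class_default, p.class_A,
                        p.class_B])


def write_crosstab_csv(tabs: list[TransformCrossTab], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frag_a", "frag_b", "n_ac_kinases", "n_nonac_kinases",
                    "behavior", "kinases"])
        for t in tabs:
            w.writerow([t.transform_key[0], t.transform_key[1], t.n_ac_kinases,
                        t.n_nonac_kinases, t.behavior,
                        ";".join(f"{k}:{'AC' if s else 'nonAC'}"
                                 for k, s in t.status_by_kinase)])
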