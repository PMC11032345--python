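"""Bundled amino-acid property tables and chemistry data.

The descriptor suite is parameterized by a fixed set of reference tables:
eight AAindex scales for the autocorrelation groups, seven three-group
physicochemical partitions for the CTD group, the seven-class residue
clustering of the conjoint-triad group, the hydrophobicity/hydrophilicity/
side-chain-mass scales used by the pseudo-amino-acid-composition groups, and
two residue distance schemes (a property-derived physicochemical distance
and the Grantham chemical distance) for the sequence-order groups.  All
tables ship as JSON/text files under ``acprop/data`` and are loaded lazily.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

#: canonical amino-acid alphabet, alphabetical one-letter order
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


def _data_path(name: str):
    return resources.files("acprop").joinpath("data", name)


def load_json(name: str) -> dict:
    with _data_path(name).open() as fh:
        return json.load(fh)


def _as_array(table: dict[str, float]) -> np.ndarray:
    return np.array([float(table[a]) for a in AA_ORDER])


def standardize(values: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-SD (population) standardization over the 20 amino acids."""
    return (values - values.mean()) / values.std()


@lru_cache(maxsize=None)
def autocorrelation_properties() -> dict[str, np.ndarray]:
    """The 8 AAindex scales used by the autocorrelation groups, standardized."""
    raw = load_json("aaindex_autocorrelation.json")
    return {pid: standardize(_as_array(tab)) for pid, tab in raw.items()}


@lru_cache(maxsize=None)
def ctd_partitions() -> dict[str, dict[str, str]]:
    """Seven physicochemical attributes, each a 3-group partition of the alphabet."""
    return load_json("ctd_groups.json")


@lru_cache(maxsize=None)
def conjoint_triad_classes() -> np.ndarray:
    """Map amino-acid index -> conjoint-triad class (0..6)."""
    classes = load_json("conjoint_triad_classes.json")
    out = np.empty(20, dtype=np.int64)
    for cls, letters in classes.items():
        for a in letters:
            out[AA_INDEX[a]] = int(cls) - 1
    return out


@lru_cache(maxsize=None)
def paac_properties() -> np.ndarray:
    """Standardized (hydrophobicity, hydrophilicity, side-chain mass), shape (3, 20)."""
    raw = load_json("paac_properties.json")
    return np.stack([
        standardize(_as_array(raw["hydrophobicity"])),
        standardize(_as_array(raw["hydrophilicity"])),
        standardize(_as_array(raw["side_chain_mass"])),
    ])


@lru_cache(maxsize=None)
def physicochemical_distance_matrix() -> np.ndarray:
    """20x20 residue distance from the standardized PAAC property triple.

    d(i, j) = sqrt(mean over the three scales of the squared difference);
    zero on the diagonal, symmetric.
    """
    props = paac_properties()
    diff = props[:, :, None] - props[:, None, :]
    return np.sqrt((diff ** 2).mean(axis=0))


@lru_cache(maxsize=None)
def grantham_distance_matrix() -> np.ndarray:
    """20x20 Grantham chemical distance computed from composition/polarity/volume."""
    g = load_json("grantham_properties.json")
    c = _as_array(g["composition"])
    p = _as_array(g["polarity"])
    v = _as_array(g["volume"])
    d2 = (g["alpha"] * (c[:, None] - c[None, :]) ** 2
          + g["beta"] * (p[:, None] - p[None, :]) ** 2
          + g["gamma"] * (v[:, None] - v[None, :]) ** 2)
    return g["rho"] * np.sqrt(d2)


@lru_cache(maxsize=None)
def scaffold_library() -> tuple[str, ...]:
    """Bundled drug-like scaffold cores (SMILES with one ``[*:1]`` attachment)."""
    return _read_fragment_file("scaffolds.smi")


@lru_cache(maxsize=None)
def substituent_library() -> tuple[str, ...]:
    """Bundled small substituent fragments (<= 5 heavy atoms)."""
    return _read_fragment_file("substituents.smi")


@lru_cache(maxsize=None)
def demo_type2_smarts() -> tuple[str, ...]:
    """Bundled demo type-II kinase-inhibitor signature SMARTS."""
    return _read_fragment_file("type2_signatures.smarts")


@lru_cache(maxsize=None)
def type2_plant_fragment() -> str:
    """Fragment grafted onto synthetic decoys so they match a demo signature."""
    return _read_fragment_file("type2_plant_fragment.smi")[0]


def _read_fragment_file(name: str) -> tuple[str, ...]:
    # '#' is a bond symbol in SMILES/SMARTS: treat it as a comment only at the
    # start of a line or when preceded by whitespace
    out = []
    with _data_path(name).open() as fh:
        for line in fh:
            line = _strip_comment(line)
            if line:
                out.append(line)
    return tuple(out)


def _strip_comment(line: str) -> str:
    if line.lstrip().startswith("#"):
        return ""
    for i, ch in enumerate(line):
        if ch == "#" and i > 0 and line[i - 1].isspace():
            return line[:i].strip()
    return line.strip()


@lru_cache(maxsize=None)
def kinase_ac_survey():
    """Published survey of 80 kinases: inhibitor/MMP/AC counts and ACs/MMPs%.

    Columns: kinase, uniprot, aa_count, n_structures, n_inhibitors, n_mmps,
    n_acs, acs_over_mmps_pct, test_set.
    """
    import pandas as pd

    with _data_path("kinase_ac_survey.csv").open() as fh:
        return pd.read_csv(fh)
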