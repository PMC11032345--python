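"""Twelve-group protein sequence descriptor suite (9920 named features).

Given an amino-acid sequence the suite computes, in a fixed group order:

====================  ====  =============================================
group                 dim   content
====================  ====  =============================================
aac                     20  amino-acid composition, count / N
dipeptide              400  dipeptide composition, count / (N - 1)
tripeptide            8000  tripeptide composition, count / (N - 2)
moreau_broto           240  normalized Moreau-Broto autocorrelation,
                            8 AAindex scales x lag 1..30
moran                  240  Moran autocorrelation, same scales/lags
geary                  240  Geary autocorrelation, same scales/lags
ctd                    147  composition (21) + transition (21) +
                            distribution (105) over 7 attribute partitions
conjoint_triad         343  7-class residue triad frequencies / (N - 2)
socn                    60  sequence-order-coupling numbers, 2 distance
                            schemes x lag 1..30
qso                    100  quasi-sequence-order, (20 + 30) per scheme
paac                    50  pseudo-amino-acid composition, 20 + lambda 30
apaac                   80  amphiphilic PAAC, 20 + 2 x lambda 30
====================  ====  =============================================

The concatenation is exactly 9920 features with unique, stable names.
Tripeptide features are named by their residues (e.g. ``GTT``), Moran
features by scale and lag (e.g. ``CHAM820101.lag6``) and CTD features in
the ``prop{k}.G{g}[.residue{r}]`` convention, so published descriptor
names are directly addressable as columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from . import aadata
from .aadata import AA_INDEX, AA_ORDER

DEFAULT_NLAG = 30
DEFAULT_LAMBDA = 30
QSO_WEIGHT = 0.1
PAAC_WEIGHT = 0.05

#: fixed group order and dimensions; the concatenation sums to 9920
GROUP_DIMS: dict[str, int] = {
    "aac": 20,
    "dipeptide": 400,
    "tripeptide": 8000,
    "moreau_broto": 240,
    "moran": 240,
    "geary": 240,
    "ctd": 147,
    "conjoint_triad": 343,
    "socn": 60,
    "qso": 100,
    "paac": 50,
    "apaac": 80,
}
TOTAL_DESCRIPTORS = sum(GROUP_DIMS.values())  # 9920


class SequenceAlphabetError(ValueError):
    """Sequence contains letters outside the 20 canonical amino acids."""


class SequenceLengthError(ValueError):
    """Sequence too short for the requested descriptor group."""


def _encode(sequence: str, drop_noncanonical: bool = False) -> np.ndarray:
    seq = sequence.strip().upper()
    if drop_noncanonical:
        seq = "".join(a for a in seq if a in AA_INDEX)
    bad = sorted(set(seq) - set(AA_ORDER))
    if bad:
        raise SequenceAlphabetError(
            f"non-canonical residue letters {bad}; pass drop_noncanonical=True to drop them"
        )
    if not seq:
        raise SequenceLengthError("empty sequence")
    return np.fromiter((AA_INDEX[a] for a in seq), dtype=np.int64, count=len(seq))


@dataclass(frozen=True)
class ProteinSeq:
    """A kinase amino-acid sequence over the 20 canonical letters."""

    kinase_id: str
    sequence: str

    def __post_init__(self):
        _encode(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DescriptorVector:
    """Named, fixed-order 9920-dimensional descriptor vector for one protein."""

    kinase_id: str
    names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.names)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.kinase_id)


def _seq_array(seq) -> np.ndarray:
    if isinstance(seq, ProteinSeq):
        return _encode(seq.sequence)
    if isinstance(seq, np.ndarray):
        return seq
    return _encode(seq)


# ---------------------------------------------------------------------------
# composition groups

@lru_cache(maxsize=None)
def _kmer_names(k: int) -> tuple[str, ...]:
    return tuple("".join(t) for t in itertools.product(AA_ORDER, repeat=k))


def _kmer_composition(idx: np.ndarray, k: int) -> np.ndarray:
    n = len(idx)
    if n < k:
        raise SequenceLengthError(f"need length >= {k} for {k}-mer composition")
    codes = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        codes = codes * 20 + idx[j:n - k + 1 + j]
    return np.bincount(codes, minlength=20 ** k) / (n - k + 1)


def composition_descriptors(seq) -> dict[str, float]:
    """AAC + dipeptide + tripeptide composition (8420 values, each block sums to 1)."""
    idx = _seq_array(seq)
    out: dict[str, float] = {}
    for k in (1, 2, 3):
        out.update(zip(_kmer_names(k), _kmer_composition(idx, k)))
    return out


# ---------------------------------------------------------------------------
# autocorrelation groups

_AC_KINDS = ("moreau_broto", "moran", "geary")


def autocorrelation(seq, kind: str, properties: dict[str, np.ndarray] | None = None,
                    nlag: int = DEFAULT_NLAG) -> dict[str, float]:
    """Lag-based autocorrelation descriptors for one kind.

    ``moreau_broto``: AC(d) = sum_i p(i) p(i+d) / (N - d) with standardized p.
    ``moran``:  I(d) = [sum_i (p(i)-pbar)(p(i+d)-pbar) / (N-d)]
                        / [sum_i (p(i)-pbar)^2 / N]
    ``geary``:  C(d) = [sum_i (p(i)-p(i+d))^2 / (2 (N-d))]
                        / [sum_i (p(i)-pbar)^2 / (N-1)]

    Moran and Geary return 0 at every lag when the property variance over the
    sequence is zero (homopolymer convention).
    """
    if kind not in _AC_KINDS:
        raise ValueError(f"unknown autocorrelation kind {kind!r}")
    idx = _seq_array(seq)
    n = len(idx)
    if n <= nlag:
        raise SequenceLengthError(f"{kind} autocorrelation needs length > {nlag}, got {n}")
    if properties is None:
        properties = aadata.autocorrelation_properties()
    out: dict[str, float] = {}
    for pid, scale in properties.items():
        p = scale[idx]
        pbar = p.mean()
        dev = p - pbar
        ss = float(dev @ dev)
        if ss <= 1e-12 * n:  # zero-variance convention, robust to roundoff
            ss = 0.0
        for d in range(1, nlag + 1):
            a, b = p[:-d], p[d:]
            if kind == "moreau_broto":
                val = float(a @ b) / (n - d)
                name = f"MoreauBroto.{pid}.lag{d}"
            elif kind == "moran":
                name = f"{pid}.lag{d}"
                if ss == 0.0:
                    val = 0.0
                else:
                    val = (float((a - pbar) @ (b - pbar)) / (n - d)) / (ss / n)
            else:
                name = f"Geary.{pid}.lag{d}"
                if ss == 0.0:
                    val = 0.0
                else:
                    val = (float(((a - b) ** 2).sum()) / (2 * (n - d))) / (ss / (n - 1))
            out[name] = val
    return out


# ---------------------------------------------------------------------------
# CTD

_DIST_FRACS = (0, 25, 50, 75, 100)


def ctd(seq) -> dict[str, float]:
    """Composition/transition/distribution descriptors (147 values).

    Seven physicochemical attributes, each partitioning the alphabet into
    three groups.  Composition is the residue fraction per group; transition
    the fraction of adjacent pairs crossing a given group boundary;
    distribution the position (as % of N) of the first, 25%, 50%, 75% and
    100% occurrence of each group.  A group absent from the sequence
    contributes five zero distribution values.
    """
    idx = _seq_array(seq)
    n = len(idx)
    out: dict[str, float] = {}
    comp_names, tr_names, dist_names = [], [], []
    comp_vals, tr_vals, dist_vals = [], [], []
    for pk, part in aadata.ctd_partitions().items():
        grp = np.empty(20, dtype=np.int64)
        for g in (1, 2, 3):
            for a in part[f"G{g}"]:
                grp[AA_INDEX[a]] = g
        gs = grp[idx]
        for g in (1, 2, 3):
            comp_names.append(f"{pk}.G{g}")
            comp_vals.append(float((gs == g).sum()) / n)
        pairs = np.stack([gs[:-1], gs[1:]])
        lo, hi = pairs.min(axis=0), pairs.max(axis=0)
        for g, h in ((1, 2), (1, 3), (2, 3)):
            tr_names.append(f"{pk}.Tr{g}{h}{h}{g}")
            tr_vals.append(float(((lo == g) & (hi == h)).sum()) / (n - 1) if n > 1 else 0.0)
        for g in (1, 2, 3):
            pos = np.flatnonzero(gs == g) + 1  # 1-based
            for frac in _DIST_FRACS:
                dist_names.append(f"{pk}.G{g}.residue{frac}")
                if len(pos) == 0:
                    dist_vals.append(0.0)
                else:
                    k = 1 if frac == 0 else int(np.ceil(frac / 100 * len(pos)))
                    dist_vals.append(100.0 * pos[k - 1] / n)
    for names, vals in ((comp_names, comp_vals), (tr_names, tr_vals), (dist_names, dist_vals)):
        out.update(zip(names, vals))
    return out


# ---------------------------------------------------------------------------
# conjoint triad

def conjoint_triad(seq) -> dict[str, float]:
    """Class-triad frequencies over the N-2 windows, normalized by (N-2)."""
    idx = _seq_array(seq)
    n = len(idx)
    if n < 3:
        raise SequenceLengthError("conjoint triad needs length >= 3")
    cls = aadata.conjoint_triad_classes()[idx]
    codes = cls[:-2] * 49 + cls[1:-1] * 7 + cls[2:]
    freq = np.bincount(codes, minlength=343) / (n - 2)
    names = [f"CT.{a + 1}{b + 1}{c + 1}"
             for a in range(7) for b in range(7) for c in range(7)]
    return dict(zip(names, freq))


# ---------------------------------------------------------------------------
# sequence-order groups

_SCHEMES = ("phys", "Grantham")


def _distance_matrices() -> dict[str, np.ndarray]:
    return {"phys": aadata.physicochemical_distance_matrix(),
            "Grantham": aadata.grantham_distance_matrix()}


def sequence_order(seq, nlag: int = DEFAULT_NLAG, weight: float = QSO_WEIGHT) -> dict[str, float]:
    """Sequence-order-coupling numbers (60) + quasi-sequence-order (100).

    For each residue-distance scheme, tau_d = sum_i d(R_i, R_{i+d})^2 for
    d = 1..nlag.  The QSO block per scheme is 20 composition terms
    f_a / (1 + w sum tau) followed by nlag coupling terms
    w tau_d / (1 + w sum tau), with f the residue frequencies.
    """
    idx = _seq_array(seq)
    n = len(idx)
    if n <= nlag:
        raise SequenceLengthError(f"sequence-order descriptors need length > {nlag}, got {n}")
    freqs = np.bincount(idx, minlength=20) / n
    out: dict[str, float] = {}
    taus: dict[str, np.ndarray] = {}
    for scheme, dm in _distance_matrices().items():
        tau = np.array([float((dm[idx[:-d], idx[d:]] ** 2).sum()) for d in range(1, nlag + 1)])
        taus[scheme] = tau
        for d, t in enumerate(tau, start=1):
            out[f"SOCN.{scheme}.lag{d}"] = t
    for scheme in _SCHEMES:
        tau = taus[scheme]
        denom = 1.0 + weight * tau.sum()
        for a, f in zip(AA_ORDER, freqs):
            out[f"QSO.{scheme}.{a}"] = f / denom
        for d, t in enumerate(tau, start=1):
            out[f"QSO.{scheme}.lag{d}"] = weight * t / denom
    return out


# ---------------------------------------------------------------------------
# pseudo-amino-acid composition groups

def pseudo_aac(seq, lam: int = DEFAULT_LAMBDA, weight: float = PAAC_WEIGHT) -> dict[str, float]:
    """Pseudo-AAC (20 + lambda) and amphiphilic pseudo-AAC (20 + 2 lambda).

    PAAC couples residues i and i+d through the mean squared difference of
    three standardized scales (hydrophobicity, hydrophilicity, side-chain
    mass); APAAC uses the lag products of the hydrophobicity (Hb) and
    hydrophilicity (Hl) scales separately.  Both use Chou's weighting.
    """
    idx = _seq_array(seq)
    n = len(idx)
    if n <= lam:
        raise SequenceLengthError(f"pseudo-AAC needs length > {lam}, got {n}")
    props = aadata.paac_properties()
    h1, h2, h3 = (props[k][idx] for k in range(3))
    freqs = np.bincount(idx, minlength=20) / n
    out: dict[str, float] = {}

    theta = np.array([
        float(((h1[d:] - h1[:-d]) ** 2 + (h2[d:] - h2[:-d]) ** 2
               + (h3[d:] - h3[:-d]) ** 2).sum()) / (3 * (n - d))
        for d in range(1, lam + 1)
    ])
    denom = 1.0 + weight * theta.sum()
    for a, f in zip(AA_ORDER, freqs):
        out[f"PAAC.{a}"] = f / denom
    for d, t in enumerate(theta, start=1):
        out[f"PAAC.lambda{d}"] = weight * t / denom

    tau_hb = np.array([float(h1[:-d] @ h1[d:]) / (n - d) for d in range(1, lam + 1)])
    tau_hl = np.array([float(h2[:-d] @ h2[d:]) / (n - d) for d in range(1, lam + 1)])
    denom = 1.0 + weight * (tau_hb.sum() + tau_hl.sum())
    for a, f in zip(AA_ORDER, freqs):
        out[f"APAAC.{a}"] = f / denom
    for d, t in enumerate(tau_hb, start=1):
        out[f"APAAC.Hb.lambda{d}"] = weight * t / denom
    for d, t in enumerate(tau_hl, start=1):
        out[f"APAAC.Hl.lambda{d}"] = weight * t / denom
    return out


# ---------------------------------------------------------------------------
# full vector

def full_descriptor_vector(seq, kinase_id: str | None = None) -> DescriptorVector:
    """Concatenate the twelve groups into one 9920-feature vector."""
    if isinstance(seq, ProteinSeq):
        kid = kinase_id or seq.kinase_id
    else:
        kid = kinase_id or ""
    idx = _seq_array(seq)
    if len(idx) <= DEFAULT_NLAG:
        raise SequenceLengthError(
            f"full descriptor vector needs length > {DEFAULT_NLAG}, got {len(idx)}")
    parts: dict[str, float] = {}
    parts.update(composition_descriptors(idx))
    for kind in _AC_KINDS:
        parts.update(autocorrelation(idx, kind))
    parts.update(ctd(idx))
    parts.update(conjoint_triad(idx))
    parts.update(sequence_order(idx))
    parts.update(pseudo_aac(idx))
    names = tuple(parts)
    values = np.fromiter(parts.values(), dtype=float, count=len(parts))
    if len(names) != TOTAL_DESCRIPTORS:
        raise AssertionError(
            f"descriptor concatenation produced {len(names)} != {TOTAL_DESCRIPTORS}")
    if not np.all(np.isfinite(values)):
        raise AssertionError("non-finite descriptor values")
    return DescriptorVector(kid, names, values)


def group_manifest() -> dict[str, tuple[int, int]]:
    """Map group name -> (start, stop) column range in the full vector."""
    manifest = {}
    start = 0
    for g, dim in GROUP_DIMS.items():
        manifest[g] = (start, start + dim)
        start += dim
    return manifest


def descriptor_matrix(proteins) -> pd.DataFrame:
    """Wide feature matrix (rows = kinases, 9920 named columns)."""
    rows = [full_descriptor_vector(p).to_series() for p in proteins]
    if not rows:
        raise ValueError("no proteins given")
    return pd.DataFrame(rows)


def read_fasta(path) -> list[ProteinSeq]:
    """Read kinase sequences from FASTA; the record id is the kinase id."""
    from Bio import SeqIO

    return [ProteinSeq(rec.id.split("|")[0], str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
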