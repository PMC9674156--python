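"""Core domain containers shared across the package.

Coordinates are 0-based internally; all on-disk formats are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical one-hot amino-acid order (alphabetical single-letter codes).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Column order of a PSI-BLAST ASCII PSSM.
PSSM_ORDER = "ARNDCQEGHILKMFPSTWVY"

#: The five disordered molecular function categories, in fixed report order.
FUNCTIONS = ("assembler", "chaperone", "display_site", "effector", "scavenger")

#: All label tracks: binary disorder plus the five functions.
TRACKS = ("disorder",) + FUNCTIONS

#: Residues outside the standard alphabet that are collapsed to 'X'.
NONSTANDARD = set("UOBZJ")


@dataclass
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(AA_ORDER) - {"X"}
        if bad:
            raise ValueError(f"illegal residues {sorted(bad)} in record {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def one_hot(self) -> np.ndarray:
        """(L, 20) one-hot matrix; 'X' rows are all zero."""
        Z = np.zeros((self.length, 20))
        for i, a in enumerate(self.sequence):
            if a != "X":
                Z[i, AA_INDEX[a]] = 1.0
        return Z


@dataclass
class SequenceProfile:
    """Per-residue evolutionary profile: 20 PSSM columns ++ 20 HHM emissions."""

    record_id: str
    X: np.ndarray  # (L, 40)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != 40:
            raise ValueError("sequence profile must be an L x 40 matrix")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite entries in sequence profile")
        hhm = self.X[:, 20:]
        if hhm.min() < 0 or hhm.max() > 1:
            raise ValueError("HHM emission columns must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.X.shape[0]


@dataclass
class ContactMap:
    """Symmetric, non-negative L x L residue-residue coupling matrix."""

    record_id: str
    Y: np.ndarray

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.Y.ndim != 2 or self.Y.shape[0] != self.Y.shape[1]:
            raise ValueError("contact map must be square")
        if not np.isfinite(self.Y).all():
            raise ValueError("non-finite entries in contact map")
        if np.abs(self.Y - self.Y.T).max() > 1e-6:
            raise ValueError("contact map must be symmetric (tolerance 1e-6)")
        if self.Y.min() < 0:
            raise ValueError("contact map entries must be non-negative")

    @property
    def length(self) -> int:
        return self.Y.shape[0]


@dataclass
class MotifPWM:
    """Letter-probability matrix of a linear motif (rows are positions)."""

    name: str
    M: np.ndarray  # (l, 20) in AA_ORDER

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.ndim != 2 or self.M.shape[1] != 20 or self.M.shape[0] < 1:
            raise ValueError("PWM must be an l x 20 matrix with l >= 1")
        if self.M.min() < 0 or self.M.max() > 1:
            raise ValueError("PWM entries must lie in [0, 1]")
        rs = self.M.sum(axis=1)
        if np.abs(rs - 1.0).max() > 1e-4:
            raise ValueError(f"PWM {self.name!r} rows must sum to 1 (tolerance 1e-4)")

    @property
    def length(self) -> int:
        return self.M.shape[0]

    def consensus(self) -> str:
        return "".join(AA_ORDER[j] for j in self.M.argmax(axis=1))


@dataclass
class LabelTrack:
    record_id: str
    track_name: str
    y: np.ndarray  # (L,) of {0,1}

    def __post_init__(self):
        if self.track_name not in TRACKS:
            raise ValueError(f"unknown track {self.track_name!r}")
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.y.ndim != 1 or not np.isin(self.y, (0, 1)).all():
            raise ValueError("label track values must be 0/1")


@dataclass
class PropensityTrack:
    """Per-residue scores in (0,1), optionally binarised at a threshold."""

    record_id: str
    P: np.ndarray
    threshold: float | None = None
    calls: np.ndarray | None = None

    def __post_init__(self):
        self.P = np.clip(np.asarray(self.P, dtype=np.float64), 1e-7, 1 - 1e-7)
        if self.P.ndim != 1:
            raise ValueError("propensity track must be a vector")
        if self.threshold is not None and self.calls is None:
            self.calls = (self.P > self.threshold).astype(np.int64)

    @property
    def length(self) -> int:
        return self.P.shape[0]


@dataclass
class ProteinData:
    """One fully-profiled protein: the unit consumed by training and prediction."""

    record: ProteinRecord
    profile: SequenceProfile
    contacts: ContactMap
    labels: dict[str, LabelTrack] = field(default_factory=dict)

    def __post_init__(self):
        L = self.record.length
        if self.profile.length != L or self.contacts.length != L:
            raise ValueError(f"profile/contact length mismatch for {self.record.id!r}")
        for t in self.labels.values():
            if t.y.shape[0] != L:
                raise ValueError(f"label length mismatch for {self.record.id!r}")


def build_sequence_profile(record: ProteinRecord, pssm: np.ndarray,
                           hhm: np.ndarray) -> SequenceProfile:
    """Assemble the L x 40 input from raw PSSM and HHM blocks.

    Rows at 'X' residues are zeroed so unknown residues contribute nothing.
    """
    pssm = np.asarray(pssm, dtype=np.float64)
    hhm = np.asarray(hhm, dtype=np.float64)
    L = record.length
    if pssm.shape != (L, 20) or hhm.shape != (L, 20):
        raise ValueError("PSSM/HHM shape must be (L, 20)")
    X = np.concatenate([pssm, hhm], axis=1)
    for i, a in enumerate(record.sequence):
        if a == "X":
            X[i, :] = 0.0
    return SequenceProfile(record.id, X)
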