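"""Readers and writers for every on-disk format the tool touches.

FASTA; PSI-BLAST ASCII PSSM; HH-suite .hhm emission profiles; CCMpred flat
coupling matrices; MEME minimal motif files; tab-separated label and
prediction files.  Parsing and validation only — no modelling here.

All files use 1-based residue coordinates; in-memory arrays are 0-based.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .types import (AA_ORDER, NONSTANDARD, PSSM_ORDER, TRACKS, LabelTrack,
                    MotifPWM, PropensityTrack, ProteinRecord)

__all__ = [
    "read_fasta", "write_fasta", "read_pssm", "write_pssm", "read_hhm",
    "write_hhm", "read_ccmpred", "write_ccmpred", "read_meme_motifs",
    "write_meme_motifs", "read_labels", "write_labels", "write_predictions",
    "read_predictions",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records; normalises case and maps U/O/B/Z/J to 'X'.

    Gap characters and any letter outside the 20-standard+X alphabet (after
    mapping) are rejected; duplicate ids are an error.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        entries = list(SeqIO.parse(handle, "fasta"))
    for entry in entries:
        if entry.id in seen:
            raise ParseError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        if "-" in seq or "." in seq:
            raise ParseError(f"{path}: gap characters in record {entry.id!r}")
        if any(c in NONSTANDARD for c in seq):
            warnings.warn(f"record {entry.id!r}: non-standard residues mapped to 'X'")
            seq = "".join("X" if c in NONSTANDARD else c for c in seq)
        bad = set(seq) - set(AA_ORDER) - {"X"}
        if bad:
            raise ParseError(f"{path}: illegal characters {sorted(bad)} "
                             f"in record {entry.id!r}")
        records.append(ProteinRecord(entry.id, seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, r.length, width):
                fh.write(r.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(path, expected_length: int | None = None) -> np.ndarray:
    """Parse the 20 log-odds columns of a PSI-BLAST ASCII PSSM into (L, 20).

    Columns come back in the fixed alphabet order of the file header
    (A R N D C Q E G H I L K M F P S T W V Y).
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    expect_idx = 1
    for ln, line in enumerate(lines, start=1):
        toks = line.split()
        if len(toks) < 22 or not toks[0].isdigit():
            continue
        if toks[1] not in AA_ORDER and toks[1] != "X":
            continue
        if int(toks[0]) != expect_idx:
            raise ParseError(f"{path}:{ln}: residue index {toks[0]} out of order")
        try:
            rows.append([float(v) for v in toks[2:22]])
        except ValueError as e:
            raise ParseError(f"{path}:{ln}: non-numeric PSSM cell") from e
        expect_idx += 1
    if not rows:
        raise ParseError(f"{path}: no PSSM rows found")
    mat = np.array(rows, dtype=np.float64)
    if expected_length is not None and mat.shape[0] != expected_length:
        raise ParseError(f"{path}: PSSM has {mat.shape[0]} rows, "
                         f"expected {expected_length}")
    return mat


def write_pssm(sequence: str, mat: np.ndarray, path) -> None:
    """Write an (L, 20) log-odds matrix in PSI-BLAST ASCII layout."""
    mat = np.asarray(mat)
    if mat.shape != (len(sequence), 20):
        raise ValueError("PSSM shape must be (L, 20)")
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(PSSM_ORDER) + "\n")
        for i, (aa, row) in enumerate(zip(sequence, mat), start=1):
            cells = "".join(f"{int(round(v)):4d}" for v in row)
            fh.write(f"{i:5d} {aa}  {cells}\n")


# ---------------------------------------------------------------------------
# HH-suite .hhm emission profiles


def _hhm_decode(tok: str) -> float:
    if tok == "*":
        return 0.0
    return 2.0 ** (-int(tok) / 1000.0)


def hhm_encode(p: float) -> str:
    """Inverse of the emission cell codec: probability -> integer token."""
    if p <= 0.0:
        return "*"
    return str(int(round(-1000.0 * math.log2(p))))


def read_hhm(path, expected_length: int | None = None) -> np.ndarray:
    """Parse the 20 emission-probability columns of an HH-suite .hhm file.

    Emission cells store integers v meaning probability 2^(-v/1000); '*'
    means probability zero.  Columns are in the file's alphabetical order
    (A C D E F G H I K L M N P Q R S T V W Y), which matches AA_ORDER.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    text = "".join(lines)
    if "NULL" not in text or "\nHMM" not in text and not text.startswith("HMM"):
        raise ParseError(f"{path}: missing NULL/HMM header blocks")
    in_body = False
    rows: list[list[float]] = []
    for ln, line in enumerate(lines, start=1):
        if line.startswith("HMM"):
            in_body = True
            continue
        if not in_body:
            continue
        if line.startswith("//"):
            break
        toks = line.split()
        if len(toks) >= 22 and len(toks[0]) == 1 and toks[0].isalpha() \
                and toks[1].isdigit():
            try:
                rows.append([_hhm_decode(t) for t in toks[2:22]])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: bad emission cell") from e
    if not rows:
        raise ParseError(f"{path}: no emission rows found after HMM header")
    mat = np.array(rows, dtype=np.float64)
    if expected_length is not None and mat.shape[0] != expected_length:
        raise ParseError(f"{path}: HHM has {mat.shape[0]} rows, "
                         f"expected {expected_length}")
    return mat


def write_hhm(name: str, sequence: str, emissions: np.ndarray, path) -> None:
    """Write an (L, 20) emission-probability matrix as a minimal .hhm file."""
    emissions = np.asarray(emissions)
    if emissions.shape != (len(sequence), 20):
        raise ValueError("HHM emission shape must be (L, 20)")
    with open(path, "w") as fh:
        fh.write("HHsearch 1.5\n")
        fh.write(f"NAME  {name}\n")
        fh.write(f"LENG  {len(sequence)}\n")
        fh.write("NULL   " + " ".join(["3000"] * 20) + "\n")
        fh.write("HMM    " + "\t".join(AA_ORDER) + "\n")
        fh.write("       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\n")
        fh.write("       0\t*\t*\t0\t*\t0\t*\t0\n")
        for i, (aa, row) in enumerate(zip(sequence, emissions), start=1):
            cells = "\t".join(hhm_encode(p) for p in row)
            fh.write(f"{aa} {i}\t{cells}\t{i}\n")
            fh.write("       0\t*\t*\t*\t*\t*\t*\t0\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# CCMpred coupling matrices


def read_ccmpred(path, record_id: str = "") -> np.ndarray:
    """Read a whitespace-separated L x L coupling matrix.

    Asymmetry beyond 1e-3 and negative entries are repaired (symmetrise,
    clip) with a warning; non-square input is an error.
    """
    mat = np.loadtxt(path, dtype=np.float64, ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ParseError(f"{path}: coupling matrix is {mat.shape[0]}x{mat.shape[1]}, "
                         "expected square")
    asym = np.abs(mat - mat.T).max()
    if asym > 1e-3:
        warnings.warn(f"{path}: coupling matrix asymmetry {asym:.3g}; symmetrised")
    mat = 0.5 * (mat + mat.T)
    if mat.min() < 0:
        warnings.warn(f"{path}: negative couplings clipped to 0")
        mat = np.clip(mat, 0.0, None)
    return mat


def write_ccmpred(mat: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(mat), fmt="%.6f", delimiter="\t")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme_motifs(path) -> list[MotifPWM]:
    """Parse a MEME minimal-format motif file with the 20-letter protein alphabet.

    Rows off unity by <= 1e-3 are renormalised; larger deviations are errors.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    alphabet = None
    motifs: list[MotifPWM] = []
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("ALPHABET="):
            alphabet = line.split("=", 1)[1].strip()
        elif line.startswith("MOTIF"):
            toks = line.split()
            name = toks[1] if len(toks) > 1 else f"motif_{len(motifs) + 1}"
            # seek the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].startswith("letter-probability"):
                if lines[j].startswith("MOTIF"):
                    raise ParseError(f"{path}: motif {name!r} has no "
                                     "letter-probability matrix")
                j += 1
            if j == len(lines):
                raise ParseError(f"{path}: motif {name!r} has no "
                                 "letter-probability matrix")
            header = lines[j]
            alength, w = 20, 0
            toks = header.replace("=", "= ").split()
            for key, val in zip(toks, toks[1:]):
                if key == "alength=":
                    alength = int(val)
                if key == "w=":
                    w = int(val)
            if alength != 20:
                raise ParseError(f"{path}: motif {name!r} alphabet length "
                                 f"{alength}, expected 20 (protein)")
            rows = []
            for k in range(j + 1, j + 1 + w):
                if k >= len(lines):
                    raise ParseError(f"{path}: motif {name!r} truncated")
                vals = [float(v) for v in lines[k].split()]
                if len(vals) != 20:
                    raise ParseError(f"{path}: motif {name!r} row has "
                                     f"{len(vals)} columns")
                rows.append(vals)
            M = np.array(rows, dtype=np.float64)
            rs = M.sum(axis=1)
            if np.abs(rs - 1.0).max() > 1e-3:
                raise ParseError(f"{path}: motif {name!r} row sums off unity "
                                 f"by {np.abs(rs - 1.0).max():.3g}")
            M = M / rs[:, None]
            motifs.append(MotifPWM(name, M))
            i = j + w
        i += 1
    if alphabet is not None:
        if set(alphabet) != set(AA_ORDER):
            raise ParseError(f"{path}: alphabet {alphabet!r} is not the "
                             "20-letter protein alphabet")
    if not motifs:
        raise ParseError(f"{path}: no MOTIF blocks found")
    return motifs


def write_meme_motifs(motifs: list[MotifPWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {AA_ORDER}\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 20 w= {m.length} "
                     f"nsites= 20 E= 0\n")
            for row in m.M:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# label tracks and prediction files


def read_labels(path, records: dict[str, ProteinRecord] | None = None) -> list[LabelTrack]:
    """Read tab-separated label tracks: record id, track name, 0/1 string."""
    path = Path(path)
    tracks: list[LabelTrack] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{ln}: expected 3 tab-separated fields")
            rid, name, bits = parts
            if name not in TRACKS:
                raise ParseError(f"{path}:{ln}: unknown track {name!r}")
            if set(bits) - {"0", "1"}:
                raise ParseError(f"{path}:{ln}: label string must be 0/1")
            if records is not None:
                rec = records.get(rid)
                if rec is None:
                    raise ParseError(f"{path}:{ln}: unknown record id {rid!r}")
                if len(bits) != rec.length:
                    raise ParseError(f"{path}:{ln}: label length {len(bits)} != "
                                     f"sequence length {rec.length}")
            tracks.append(LabelTrack(rid, name, np.fromiter(bits, dtype=np.int64)))
    return tracks


def write_labels(tracks: list[LabelTrack], path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            fh.write(f"{t.record_id}\t{t.track_name}\t"
                     + "".join(str(int(v)) for v in t.y) + "\n")


def write_predictions(tracks: list[PropensityTrack], sequences: dict[str, str],
                      path) -> None:
    """One row per residue: 1-based index, residue letter, propensity (6 dp),
    binary call.  The decision threshold is carried in a header comment."""
    with open(path, "w") as fh:
        for t in tracks:
            thr = "NA" if t.threshold is None else f"{t.threshold:.6f}"
            fh.write(f"# record={t.record_id} threshold={thr}\n")
            seq = sequences[t.record_id]
            if len(seq) != t.length:
                raise ValueError(f"sequence/propensity length mismatch for "
                                 f"{t.record_id!r}")
            for i, (aa, p) in enumerate(zip(seq, t.P), start=1):
                call = "NA" if t.calls is None else str(int(t.calls[i - 1]))
                fh.write(f"{i}\t{aa}\t{p:.6f}\t{call}\n")


def read_predictions(path) -> list[PropensityTrack]:
    """Inverse of :func:`write_predictions` (propensities to 6 decimals)."""
    tracks: list[PropensityTrack] = []
    rid, thr, ps, calls = None, None, [], []

    def flush():
        if rid is not None:
            c = None if any(v is None for v in calls) else np.array(calls)
            tracks.append(PropensityTrack(rid, np.array(ps), thr, c))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# record="):
                flush()
                fields = dict(kv.split("=", 1) for kv in line[2:].split())
                rid = fields["record"]
                thr = None if fields["threshold"] == "NA" else float(fields["threshold"])
                ps, calls = [], []
            elif line:
                idx, _aa, p, call = line.split("\t")
                ps.append(float(p))
                calls.append(None if call == "NA" else int(call))
    flush()
    return tracks
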