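"""Synthetic proteomes with the statistical structure the model assumes.

Each simulated protein alternates ordered and disordered segments.  The two
segment types differ in amino-acid composition (disordered segments are
enriched for the disorder-promoting residues P/E/S/K/Q/A/G), in their
pseudo evolutionary profiles (PSSM-like log-odds and HMM-like emission rows
reflect the segment composition plus noise) and in their contact maps
(ordered segments carry a dense banded coupling structure, disordered
segments near-zero couplings).  Function labels are motif-driven: each of
the five function classes owns a disjoint bank of letter-probability
matrices; motifs are planted only inside disordered segments, and the
planted footprint plus a two-residue flank is labelled positive for that
function.  Function labels are therefore a subset of disorder labels by
construction, mirroring how functional residues sit inside disordered
regions of real annotation databases.

Emission rows and contact maps are quantised to their on-disk precision at
generation time so that writing a benchmark and re-reading it reproduces
the in-memory proteome exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .types import (AA_ORDER, FUNCTIONS, PSSM_ORDER, ContactMap, LabelTrack,
                    MotifPWM, ProteinData, ProteinRecord, SequenceProfile,
                    TRACKS, build_sequence_profile)

__all__ = ["SimConfig", "SimProteome", "simulate_proteome", "simulate_profiles",
           "simulate_contacts", "make_motif_banks", "write_benchmark",
           "read_benchmark"]

#: Disorder-promoting residues (enriched in disordered segments).
DISORDER_PROMOTING = "PESKQAG"
#: Order-promoting residues (enriched in ordered segments).
ORDER_PROMOTING = "WFYILVCN"

#: Uniform-ish background with a mild bias toward common residues.
_BG = np.full(20, 1.0 / 20.0)


def _segment_composition(kind: str) -> np.ndarray:
    comp = _BG.copy()
    boost = DISORDER_PROMOTING if kind == "disordered" else ORDER_PROMOTING
    for a in boost:
        comp[AA_ORDER.index(a)] *= 3.0
    return comp / comp.sum()


@dataclass
class SimConfig:
    n_proteins: int = 500
    length_range: tuple[int, int] = (60, 400)
    disorder_fraction: float = 0.3
    motifs_per_function: int = 3
    motif_length_range: tuple[int, int] = (6, 8)
    motif_plant_rate: float = 0.7       # per eligible disordered segment
    motif_flank: int = 2
    profile_noise: float = 1.0          # PSSM integer noise half-width / HHM spread
    pssm_scale: float = 2.0             # log-odds multiplier before rounding
    contact_band: int = 8
    contact_density_ordered: float = 0.8
    contact_density_disordered: float = 0.03
    mean_disordered_segment: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.length_range[0] < 20:
            raise ValueError("minimum protein length must be >= 20")
        if not 0.0 <= self.disorder_fraction <= 1.0:
            raise ValueError("disorder fraction must lie in [0, 1]")
        if not 0.0 <= self.motif_plant_rate <= 1.0:
            raise ValueError("motif plant rate must lie in [0, 1]")
        min_seg = 10
        if self.motif_length_range[1] + 2 * self.motif_flank > 2 * min_seg:
            raise ValueError("motifs too long for the minimum segment length")


@dataclass
class SimProteome:
    config: SimConfig
    items: list[ProteinData]
    motif_banks: dict[str, list[MotifPWM]]
    placements: list[dict] = field(default_factory=list)

    @property
    def motifs(self) -> list[MotifPWM]:
        return [m for f in FUNCTIONS for m in self.motif_banks[f]]


def make_motif_banks(config: SimConfig,
                     rng: np.random.Generator) -> dict[str, list[MotifPWM]]:
    """Disjoint per-function PWM banks with distinct consensus strings."""
    banks: dict[str, list[MotifPWM]] = {}
    used: set[str] = set()
    lo, hi = config.motif_length_range
    for fn in FUNCTIONS:
        bank = []
        for j in range(config.motifs_per_function):
            while True:
                l = int(rng.integers(lo, hi + 1))
                consensus = "".join(rng.choice(list(AA_ORDER), size=l))
                if consensus not in used:
                    used.add(consensus)
                    break
            M = np.full((l, 20), 0.2 / 19.0)
            for i, a in enumerate(consensus):
                M[i, AA_ORDER.index(a)] = 0.8
            bank.append(MotifPWM(f"{fn}_{j + 1}", M))
        banks[fn] = bank
    return banks


def _sample_segments(L: int, f: float, rng: np.random.Generator,
                     min_seg: int = 10,
                     mean_dis: float = 30.0) -> list[tuple[int, int, str]]:
    """Alternating (start, end, kind) segments hitting disorder fraction f
    in expectation (renewal argument: mean segment lengths in ratio f:(1-f))."""
    if f <= 0.0:
        return [(0, L, "ordered")]
    if f >= 1.0:
        return [(0, L, "disordered")]
    mean_ord = mean_dis * (1.0 - f) / f
    kind = "disordered" if rng.random() < f else "ordered"
    segs: list[tuple[int, int, str]] = []
    pos = 0
    while pos < L:
        mean = mean_dis if kind == "disordered" else mean_ord
        length = min_seg + int(rng.geometric(1.0 / max(mean - min_seg, 1.0))) - 1
        length = min(length, L - pos)
        segs.append((pos, pos + length, kind))
        pos += length
        kind = "ordered" if kind == "disordered" else "disordered"
    return segs


def simulate_profiles(record: ProteinRecord,
                      segments: list[tuple[int, int, str]],
                      config: SimConfig,
                      rng: np.random.Generator) -> SequenceProfile:
    """Pseudo PSSM + HHM profile whose rows reflect the segment composition.

    PSSM column a at residue i is round(scale * log2(p_seg(a)/p_bg(a))) plus
    integer noise drawn from {-noise..+noise}; HHM rows are the segment
    composition perturbed by Dirichlet noise, then quantised through the
    integer emission codec so the on-disk round trip is exact.
    """
    L = record.length
    pssm = np.zeros((L, 20))
    hhm = np.zeros((L, 20))
    noise = int(round(config.profile_noise))
    for start, end, kind in segments:
        comp = _segment_composition(kind)
        base = np.round(config.pssm_scale * np.log2(comp / _BG))
        # PSSM columns live in PSI-BLAST order
        base_pssm = base[[AA_ORDER.index(a) for a in PSSM_ORDER]]
        for i in range(start, end):
            row = base_pssm.copy()
            if noise > 0:
                row += rng.integers(-noise, noise + 1, size=20)
            pssm[i] = row
            if config.profile_noise > 0:
                conc = comp * 40.0 / config.profile_noise
                h = rng.dirichlet(conc)
            else:
                h = comp
            hhm[i] = _quantize_hhm(h)
    return build_sequence_profile(record, pssm, hhm)


def _quantize_hhm(p: np.ndarray) -> np.ndarray:
    # route through the exact on-disk codec so write -> read is the identity
    return np.array([pio._hhm_decode(pio.hhm_encode(v)) for v in p])


def simulate_contacts(record: ProteinRecord,
                      segments: list[tuple[int, int, str]],
                      config: SimConfig,
                      rng: np.random.Generator) -> ContactMap:
    """Banded couplings inside ordered segments, noise-floor elsewhere.

    Within an ordered segment, residues i, j couple with strength
    density * exp(-|i-j|/4) for |i-j| <= band, plus a few sparse long-range
    ordered-ordered pairs; disordered positions receive only a small noise
    floor.  The matrix is symmetric and non-negative by construction and is
    quantised to the 6-decimal on-disk precision.
    """
    L = record.length
    Y = np.zeros((L, L))
    ordered_idx = []
    for start, end, kind in segments:
        if kind != "ordered":
            continue
        ordered_idx.extend(range(start, end))
        for i in range(start, end):
            for j in range(i + 1, min(end, i + config.contact_band + 1)):
                v = config.contact_density_ordered * np.exp(-(j - i) / 4.0)
                Y[i, j] = Y[j, i] = v
    # sparse long-range couplings between ordered residues
    if len(ordered_idx) >= 4:
        n_extra = max(1, L // 50)
        for _ in range(n_extra):
            i, j = rng.choice(ordered_idx, size=2, replace=False)
            v = float(rng.uniform(0.3, 0.6))
            Y[i, j] = Y[j, i] = max(Y[i, j], v)
    # noise floor everywhere
    noise = np.abs(rng.normal(0.0, config.contact_density_disordered, (L, L)))
    noise = 0.5 * (noise + noise.T)
    np.fill_diagonal(noise, 0.0)
    Y = Y + noise
    return ContactMap(record.id, np.round(Y, 6))


def simulate_proteome(config: SimConfig) -> SimProteome:
    """Generate a fully-labelled synthetic proteome (sequences, six label
    tracks, profiles, contact maps and ground-truth motif placements)."""
    rng = np.random.default_rng(config.seed)
    banks = make_motif_banks(config, rng)
    items: list[ProteinData] = []
    placements: list[dict] = []
    lo, hi = config.length_range
    for idx in range(config.n_proteins):
        L = int(rng.integers(lo, hi + 1))
        segs = _sample_segments(L, config.disorder_fraction, rng,
                                mean_dis=config.mean_disordered_segment)
        seq = np.empty(L, dtype="<U1")
        for start, end, kind in segs:
            comp = _segment_composition(kind)
            seq[start:end] = rng.choice(list(AA_ORDER), size=end - start, p=comp)
        labels = {t: np.zeros(L, dtype=np.int64) for t in TRACKS}
        for start, end, kind in segs:
            if kind == "disordered":
                labels["disorder"][start:end] = 1
        # plant motifs inside disordered segments
        for start, end, kind in segs:
            if kind != "disordered":
                continue
            if rng.random() >= config.motif_plant_rate:
                continue
            fn = FUNCTIONS[rng.integers(len(FUNCTIONS))]
            pwm = banks[fn][rng.integers(len(banks[fn]))]
            lm = pwm.length
            flank = config.motif_flank
            s_lo = start + flank
            s_hi = end - flank - lm
            if s_hi < s_lo:
                continue
            pos = int(rng.integers(s_lo, s_hi + 1))
            for k in range(lm):
                seq[pos + k] = AA_ORDER[rng.choice(20, p=pwm.M[k])]
            labels[fn][pos - flank: pos + lm + flank] = 1
            placements.append({"record": f"sim{idx:05d}", "function": fn,
                               "motif": pwm.name, "start": pos, "end": pos + lm})
        record = ProteinRecord(f"sim{idx:05d}", "".join(seq))
        profile = simulate_profiles(record, segs, config, rng)
        contacts = simulate_contacts(record, segs, config, rng)
        tracks = {t: LabelTrack(record.id, t, labels[t]) for t in TRACKS}
        items.append(ProteinData(record, profile, contacts, tracks))
    return SimProteome(config, items, banks, placements)


# ---------------------------------------------------------------------------
# benchmark directories


def split_proteome(proteome: SimProteome, ratios=(0.6, 0.2, 0.2),
                   seed: int = 0) -> dict[str, list[ProteinData]]:
    """Deterministic train/val/test split (default 6:2:2)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proteome.items))
    n = len(order)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    idx = {"train": order[:n_train], "val": order[n_train:n_train + n_val],
           "test": order[n_train + n_val:]}
    return {k: [proteome.items[i] for i in v] for k, v in idx.items()}


def write_benchmark(proteome: SimProteome, out_dir, force: bool = False,
                    split_seed: int = 0) -> dict[str, list[str]]:
    """Emit a benchmark directory: per-split FASTA + labels + profiles, a
    MEME motif bank, and a manifest recording the generating configuration."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    splits = split_proteome(proteome, seed=split_seed)
    split_ids: dict[str, list[str]] = {}
    for split, items in splits.items():
        d = out / split
        prof = d / "profiles"
        prof.mkdir(parents=True, exist_ok=True)
        pio.write_fasta([i.record for i in items], d / "sequences.fasta")
        tracks = [i.labels[t] for i in items for t in TRACKS]
        pio.write_labels(tracks, d / "labels.tsv")
        for item in items:
            rid = item.record.id
            pio.write_pssm(item.record.sequence, item.profile.X[:, :20],
                           prof / f"{rid}.pssm")
            pio.write_hhm(rid, item.record.sequence, item.profile.X[:, 20:],
                          prof / f"{rid}.hhm")
            pio.write_ccmpred(item.contacts.Y, prof / f"{rid}.mat")
        split_ids[split] = [i.record.id for i in items]
    pio.write_meme_motifs(proteome.motifs, out / "motifs.meme")
    manifest = {"config": asdict(proteome.config), "split_seed": split_seed,
                "splits": split_ids,
                "functions": list(FUNCTIONS),
                "placements": proteome.placements}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return split_ids


def read_benchmark(bench_dir) -> tuple[dict[str, list[ProteinData]],
                                       list[MotifPWM], dict]:
    """Reconstruct a benchmark directory written by :func:`write_benchmark`."""
    bench = Path(bench_dir)
    with open(bench / "manifest.json") as fh:
        manifest = json.load(fh)
    motifs = pio.read_meme_motifs(bench / "motifs.meme")
    splits: dict[str, list[ProteinData]] = {}
    for split in ("train", "val", "test"):
        d = bench / split
        records = pio.read_fasta(d / "sequences.fasta")
        recmap = {r.id: r for r in records}
        tracks = pio.read_labels(d / "labels.tsv", recmap)
        by_rec: dict[str, dict[str, LabelTrack]] = {}
        for t in tracks:
            by_rec.setdefault(t.record_id, {})[t.track_name] = t
        items = []
        for r in records:
            pssm = pio.read_pssm(d / "profiles" / f"{r.id}.pssm", r.length)
            hhm = pio.read_hhm(d / "profiles" / f"{r.id}.hhm", r.length)
            ccm = pio.read_ccmpred(d / "profiles" / f"{r.id}.mat")
            if ccm.shape[0] != r.length:
                raise pio.ParseError(f"contact map length mismatch for {r.id!r}")
            items.append(ProteinData(
                r, build_sequence_profile(r, pssm, hhm),
                ContactMap(r.id, ccm), by_rec.get(r.id, {})))
        splits[split] = items
    return splits, motifs, manifest
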