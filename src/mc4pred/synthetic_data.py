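"""Synthetic balanced 4mC-style datasets with a planted, tunable motif.

Real 4mC benchmarks are balanced sets of 41-nt windows with the candidate
cytosine at the center, where some sequence signal distinguishes methylated
from unmethylated windows.  This generator emulates that shape: negatives
are i.i.d. background sequence with the center forced to 'C'; positives are
the same background with a noisy consensus motif planted at a random offset.

The signal strength is a single dial, ``match_prob``: each motif position
emits its consensus base with probability ``match_prob`` and one of the
other three bases uniformly otherwise.  At ``match_prob = 0.25`` (with
uniform background) the planted motif is statistically invisible and the
two classes are exchangeable; at 1.0 every positive carries the exact
consensus.  Placements that would cover the forced center 'C' or leave the
window are excluded from the uniform offset draw, so the center base never
carries class information.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqcodec import DnaWindow, validate_window, write_fasta

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Generator settings.

    ``placement_halfwidth`` bounds |offset| of the motif start from its
    anchor (``anchor_start``, default 10 for a 41-nt window: ten positions
    left of the center).
    """

    n_pos: int = 746
    n_neg: int = 746
    seq_len: int = 41
    motif: str = "GAGTCA"
    match_prob: float = 0.9
    placement_halfwidth: int = 5
    anchor_start: int | None = None
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if not 0.25 <= self.match_prob <= 1.0:
            raise ValueError("match_prob must lie in [0.25, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        self.motif = self.motif.upper()
        if set(self.motif) - set("ACGT"):
            raise ValueError("motif must be over {A, C, G, T}")
        if self.anchor_start is None:
            self.anchor_start = self.center_index - 10
        if not self.valid_starts():
            raise ValueError(
                "no valid motif placement: motif too long for the flank, or "
                "every candidate start overlaps the center"
            )

    @property
    def center_index(self) -> int:
        return (self.seq_len - 1) // 2

    def valid_starts(self) -> list[int]:
        """Motif start positions inside the window that avoid the center."""
        m = len(self.motif)
        lo = self.anchor_start - self.placement_halfwidth
        hi = self.anchor_start + self.placement_halfwidth
        return [
            s
            for s in range(max(lo, 0), min(hi, self.seq_len - m) + 1)
            if not (s <= self.center_index < s + m)
        ]


def _random_background(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """(n, seq_len) array of base characters, center forced to 'C'."""
    seqs = rng.choice(_BASES, size=(n, cfg.seq_len), p=list(cfg.background))
    seqs[:, cfg.center_index] = "C"
    return seqs


def _noisy_motif(rng: np.random.Generator, cfg: SimConfig) -> str:
    """Emit the consensus per position w.p. match_prob, else another base."""
    out = []
    for base in cfg.motif:
        if rng.random() < cfg.match_prob:
            out.append(base)
        else:
            others = [b for b in "ACGT" if b != base]
            out.append(others[rng.integers(3)])
    return "".join(out)


def simulate(cfg: SimConfig) -> tuple[list[DnaWindow], list[dict]]:
    """Generate labeled windows and a ground-truth manifest.

    Returns ``(windows, manifest)``: positives first (labels 1), then
    negatives (labels 0).  The manifest has one row per positive with its
    id, motif start offset, and the realized (noisy) motif string.  The
    output is fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    starts = cfg.valid_starts()
    windows: list[DnaWindow] = []
    manifest: list[dict] = []

    pos_seqs = _random_background(rng, cfg.n_pos, cfg)
    for i in range(cfg.n_pos):
        start = starts[rng.integers(len(starts))]
        realized = _noisy_motif(rng, cfg)
        pos_seqs[i, start : start + len(realized)] = list(realized)
        wid = f"pos_{i}"
        windows.append(DnaWindow(id=wid, sequence="".join(pos_seqs[i]), label=1))
        manifest.append({"id": wid, "motif_start": start, "realized_motif": realized})

    neg_seqs = _random_background(rng, cfg.n_neg, cfg)
    for i in range(cfg.n_neg):
        windows.append(DnaWindow(id=f"neg_{i}", sequence="".join(neg_seqs[i]), label=0))

    for w in windows:
        validate_window(w, length=cfg.seq_len)
    return windows, manifest


def write_dataset(
    windows: list[DnaWindow], manifest: list[dict], out_dir: str | Path
) -> dict[str, Path]:
    """Write pos.fasta, neg.fasta and manifest.tsv under ``out_dir``."""
    if not windows:
        raise ValueError("no windows to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pos": out_dir / "pos.fasta",
        "neg": out_dir / "neg.fasta",
        "manifest": out_dir / "manifest.tsv",
    }
    write_fasta([w for w in windows if w.label == 1], paths["pos"])
    write_fasta([w for w in windows if w.label == 0], paths["neg"])
    with open(paths["manifest"], "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["id", "motif_start", "realized_motif"], delimiter="\t"
        )
        writer.writeheader()
        writer.writerows(manifest)
    return paths
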