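"""Synthetic binary movies: generation, pixel corruption, and PBM I/O.

A movie is a closed loop of Q binary frames on the cell grid; pixel values
are spin-valued, s in {-1, +1}, with +1 the "active" pixel.  The duty cycle
d is the probability of a pixel being active at generation time.  The
successor of frame Q is frame 1, so a movie of Q frames defines exactly Q
recorded transitions.

On disk each frame is one PBM image (P1 ASCII or P4 raw); the package maps
PBM bit 1 ("black") to pixel +1 and bit 0 to -1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .topology import ConfigurationError, TorusGrid

_FRAME_RE = re.compile(r"frame_(\d+)\.pbm$")


@dataclass(frozen=True)
class Movie:
    """Closed-loop sequence of Q binary frames.

    Attributes
    ----------
    frames : np.ndarray
        Shape (Q, H, W), dtype int8, values in {-1, +1}.
    duty_cycle : float
        Generation probability of +1 (0.5 for fully random movies).
    seed : int or None
        Seed used at generation; None for movies loaded from disk.
    """

    frames: np.ndarray
    duty_cycle: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3 or f.shape[0] < 1:
            raise ConfigurationError(f"frames must be (Q, H, W) with Q >= 1, got shape {f.shape}")
        if not np.isin(f, (-1, 1)).all():
            raise ConfigurationError("frame pixels must be -1 or +1")
        object.__setattr__(self, "frames", np.ascontiguousarray(f, dtype=np.int8))

    @property
    def Q(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def flat(self) -> np.ndarray:
        """Frames flattened to (Q, N) row-major, matching cell indexing."""
        return self.frames.reshape(self.Q, -1)


def generate_movie(grid: TorusGrid, Q: int, d: float = 0.5, seed: int | None = None) -> Movie:
    """Generate Q independent random frames with P(pixel = +1) = d.

    Uses numpy's PCG64 generator, so identical (grid, Q, d, seed) inputs
    reproduce bit-identical movies across platforms.
    """
    if Q < 1:
        raise ConfigurationError(f"Q must be >= 1, got {Q}")
    if not 0.0 < d < 1.0:
        raise ConfigurationError(f"duty cycle must lie in (0, 1), got {d}")
    rng = np.random.default_rng(seed)
    frames = np.where(rng.random((Q, grid.H, grid.W)) < d, 1, -1).astype(np.int8)
    return Movie(frames=frames, duty_cycle=float(d), seed=seed)


def flip_pixels(frame: np.ndarray, f: float, seed: int | None = None) -> np.ndarray:
    """Negate exactly round(f*N) distinct pixels, chosen uniformly.

    The exact-count convention (rather than per-pixel Bernoulli flips) makes
    input-noise sweeps exact in the corrupted fraction f.  The input frame
    is not modified.
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError(f"flip fraction must lie in [0, 1], got {f}")
    frame = np.asarray(frame)
    n_flip = int(round(f * frame.size))
    out = frame.copy()
    if n_flip:
        rng = np.random.default_rng(seed)
        idx = rng.choice(frame.size, size=n_flip, replace=False)
        out.reshape(-1)[idx] *= -1
    return out


# ---------------------------------------------------------------------------
# PBM frame stacks


def _write_pbm(path: Path, frame: np.ndarray, dialect: str) -> None:
    black = np.asarray(frame) == 1  # active pixel -> PBM bit 1 (black)
    H, W = black.shape
    if dialect == "P1":
        rows = "\n".join(" ".join("1" if v else "0" for v in row) for row in black)
        path.write_text(f"P1\n{W} {H}\n{rows}\n")
    elif dialect == "P4":
        # Pillow mode "1": nonzero = white, so invert (black = bit 1 in PBM).
        Image.fromarray(~black).save(path, format="PPM")
    else:
        raise ConfigurationError(f"unknown PBM dialect {dialect!r} (use 'P1' or 'P4')")


def _read_pbm(path: Path) -> np.ndarray:
    with Image.open(path) as img:
        white = np.asarray(img.convert("1"), dtype=bool)
    return np.where(white, -1, 1).astype(np.int8)  # black -> +1


def write_movie(directory: str | Path, movie: Movie, dialect: str = "P1") -> list[Path]:
    """Write one PBM file per frame: frame_0000.pbm, frame_0001.pbm, ..."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for q in range(movie.Q):
        p = directory / f"frame_{q:04d}.pbm"
        _write_pbm(p, movie.frames[q], dialect)
        paths.append(p)
    return paths


def read_movie(directory: str | Path) -> Movie:
    """Read a numbered PBM frame stack back into a :class:`Movie`."""
    directory = Path(directory)
    files = sorted(
        (p for p in directory.iterdir() if _FRAME_RE.search(p.name)),
        key=lambda p: int(_FRAME_RE.search(p.name).group(1)),
    )
    if not files:
        raise FileNotFoundError(f"no frame_NNNN.pbm files under {directory}")
    frames = []
    shape = None
    for p in files:
        arr = _read_pbm(p)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ConfigurationError(
                f"frame {p.name} has dimensions {arr.shape}, expected {shape}"
            )
        frames.append(arr)
    return Movie(frames=np.stack(frames), seed=None)


def write_frames_csv(path: str | Path, movie: Movie) -> None:
    """Export frames as CSV: blocks of H rows of +/-1, one block per frame."""
    with open(path, "w") as fh:
        for q in range(movie.Q):
            for row in movie.frames[q]:
                fh.write(",".join(str(int(v)) for v in row) + "\n")
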