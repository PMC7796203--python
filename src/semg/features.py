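"""Multiscale singular-value permutation-entropy features of the TFM.

The modulus of the S-transform output is summarized at two scales: the
leading singular values of the whole matrix capture its global energy
structure, while the largest singular value of each contiguous block —
the matrix split into ``q`` blocks along the time axis and, separately,
``p`` blocks along the frequency axis — traces how that energy is
distributed in time and in frequency.  Permutation entropy of the three
resulting sequences (ordinal-pattern Shannon entropy) compresses each to
a single scalar, giving the per-channel feature triple

    F = [Et, Ef, EA]

(PE of the time-block maxima, of the frequency-block maxima, and of the
global singular-value sequence).  Concatenating the triples over the four
muscle channels yields the 12-dimensional classifier input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import svdvals

from .stockwell import STConfig, stransform, tfm_modulus
from .synth import MultiChannelRecording

__all__ = [
    "PartitionConfig",
    "PEConfig",
    "MultiscaleSingularSpectrum",
    "singular_values",
    "partition_blocks",
    "multiscale_spectrum",
    "permutation_entropy",
    "channel_features",
    "dataset_features",
    "write_features",
    "read_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartitionConfig:
    """Blockwise partition of the TFM and global singular-value retention.

    ``q`` blocks along the time axis, ``p`` along the frequency axis;
    ``k_keep`` leading global singular values are retained (truncated with
    a warning if the matrix rank bound is smaller).  ``global_sequence``
    controls whether the global sequence is the descending LAPACK output
    (the conventional definition) or left exactly as computed.
    """

    q: int = 16
    p: int = 16
    k_keep: int = 20
    global_sequence: Literal["descending", "as_computed"] = "descending"

    def __post_init__(self) -> None:
        if self.q < 1 or self.p < 1:
            raise ValueError("p and q must be >= 1")
        if self.k_keep < 1:
            raise ValueError("k_keep must be >= 1")


@dataclass(frozen=True)
class PEConfig:
    """Permutation-entropy parameters: embedding dimension ``m``, delay
    ``tau`` (samples), and optional normalization by ln(m!)."""

    m: int = 3
    tau: int = 1
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")

    def min_length(self) -> int:
        return (self.m - 1) * self.tau + 1


@dataclass
class MultiscaleSingularSpectrum:
    """Global and blockwise singular-value sequences of one TFM.

    ``lambda_A``: leading global singular values, descending.
    ``lambda_t``: largest singular value of each of the q time blocks.
    ``lambda_f``: largest singular value of each of the p frequency blocks.
    """

    lambda_A: np.ndarray
    lambda_t: np.ndarray
    lambda_f: np.ndarray


def singular_values(matrix: np.ndarray) -> np.ndarray:
    """Singular values of a real matrix, descending; length min(rows, cols)."""
    a = np.atleast_2d(np.asarray(matrix, dtype=float))
    if a.size == 0:
        raise ValueError("matrix must be at least 1x1")
    if not np.all(np.isfinite(a)):
        raise ValueError("matrix contains non-finite entries")
    return svdvals(a)


def partition_blocks(
    matrix: np.ndarray,
    n_blocks: int,
    axis: Literal["time", "frequency"],
) -> list[np.ndarray]:
    """Split the TFM modulus into contiguous blocks along one axis.

    Time blocks split the columns, frequency blocks the rows.  Blocks are
    non-overlapping and exhaustive, in axis order; when the axis length is
    not divisible the leading blocks are one element larger.
    """
    a = np.atleast_2d(np.asarray(matrix))
    ax = {"time": 1, "frequency": 0}.get(axis)
    if ax is None:
        raise ValueError(f"axis must be 'time' or 'frequency', got {axis!r}")
    if not 1 <= n_blocks <= a.shape[ax]:
        raise ValueError(
            f"cannot split axis of length {a.shape[ax]} into {n_blocks} blocks"
        )
    return np.array_split(a, n_blocks, axis=ax)


def multiscale_spectrum(
    tfm_modulus: np.ndarray, cfg: PartitionConfig = PartitionConfig()
) -> MultiscaleSingularSpectrum:
    """Global + blockwise singular-value sequences of a TFM modulus."""
    a = np.atleast_2d(np.asarray(tfm_modulus, dtype=float))
    lam = singular_values(a)
    if cfg.k_keep > lam.size:
        logger.warning(
            "k_keep=%d exceeds available singular values (%d); truncating",
            cfg.k_keep, lam.size,
        )
    lam_a = lam[: cfg.k_keep]
    if cfg.global_sequence == "descending":
        lam_a = np.sort(lam_a)[::-1]
    lam_t = np.array([svdvals(b)[0] for b in partition_blocks(a, cfg.q, "time")])
    lam_f = np.array([svdvals(b)[0] for b in partition_blocks(a, cfg.p, "frequency")])
    return MultiscaleSingularSpectrum(lambda_A=lam_a, lambda_t=lam_t, lambda_f=lam_f)


def _ordinal_patterns(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Integer codes of the ordinal pattern of every delay-embedded window.

    Ties are broken by position: equal values keep their original order
    (earlier index = lower rank), so the mapping is deterministic.
    """
    n_win = x.size - (m - 1) * tau
    idx = np.arange(n_win)[:, None] + tau * np.arange(m)[None, :]
    windows = x[idx]
    perms = np.argsort(windows, axis=1, kind="stable")
    # encode each permutation as an integer in factorial base
    codes = np.zeros(n_win, dtype=np.int64)
    for k in range(m):
        codes = codes * m + perms[:, k]
    return codes


def permutation_entropy(sequence: Sequence[float], cfg: PEConfig = PEConfig()) -> float:
    """Permutation entropy of a sequence, in nats.

    Each length-``m`` delay-embedded window is mapped to its ordinal (rank)
    pattern; H is the Shannon entropy of the empirical pattern
    distribution, bounded by ln(m!).  With ``normalize`` the value is
    divided by ln(m!) so it lies in [0, 1].
    """
    x = np.asarray(sequence, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("sequence contains non-finite values")
    if x.size < cfg.min_length():
        raise ValueError(
            f"sequence of length {x.size} too short for m={cfg.m}, "
            f"tau={cfg.tau}; need at least {cfg.min_length()}"
        )
    codes = _ordinal_patterns(x, cfg.m, cfg.tau)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / codes.size
    h = float(-np.sum(p * np.log(p)))
    if cfg.normalize:
        h /= math.log(math.factorial(cfg.m))
    return h


def channel_features(
    tfm_modulus: np.ndarray,
    partition_cfg: PartitionConfig = PartitionConfig(),
    pe_cfg: PEConfig = PEConfig(),
) -> tuple[float, float, float]:
    """Feature triple (Et, Ef, EA) for one channel's TFM modulus."""
    spec = multiscale_spectrum(tfm_modulus, partition_cfg)
    et = permutation_entropy(spec.lambda_t, pe_cfg)
    ef = permutation_entropy(spec.lambda_f, pe_cfg)
    ea = permutation_entropy(spec.lambda_A, pe_cfg)
    return et, ef, ea


def dataset_features(
    recordings: Sequence[MultiChannelRecording],
    st_cfg: STConfig = STConfig(),
    partition_cfg: PartitionConfig = PartitionConfig(),
    pe_cfg: PEConfig = PEConfig(),
) -> pd.DataFrame:
    """Feature table for a dataset: one row per trial, 3 columns per channel.

    Columns are ``<channel>_Et``, ``<channel>_Ef``, ``<channel>_EA`` in
    recording channel order, preceded by ``trial_id`` and ``label``
    (empty when unlabelled).  Row order preserves input order.
    """
    if len(recordings) == 0:
        return pd.DataFrame(columns=["trial_id", "label"])
    first = recordings[0]
    for i, rec in enumerate(recordings):
        if rec.n_channels != first.n_channels or rec.fs != first.fs:
            raise ValueError(
                f"recording {i} has {rec.n_channels} channels at fs={rec.fs}; "
                f"expected {first.n_channels} at fs={first.fs}"
            )
    cols = [f"{name}_{suffix}" for name in first.channel_names
            for suffix in ("Et", "Ef", "EA")]
    rows = []
    for i, rec in enumerate(recordings):
        feats = []
        for c in range(rec.n_channels):
            tfm = stransform(rec.samples[:, c], st_cfg)
            feats.extend(channel_features(tfm_modulus(tfm), partition_cfg, pe_cfg))
        rows.append([i, rec.label, *feats])
    return pd.DataFrame(rows, columns=["trial_id", "label", *cols])


def write_features(table: pd.DataFrame, path) -> None:
    """Write a feature table CSV (full float precision)."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)
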