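"""Descriptive succinylome characterization.

Sites-per-protein histogram, ±10-residue sequence windows around modified
lysines, position-specific residue frequencies and enrichment against the
background of all proteome lysines, and greedy motif-x-style motif
extraction (binomial test per residue/position cell; a branch is fixed only
when its p-value beats the threshold and enough windows still match).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import STANDARD_AA, SiteRecord

PAD = "X"


@dataclass(frozen=True)
class SiteWindow:
    """A modified K with its flanking residues: 2·flank+1 characters,
    center = the modified lysine, 'X'-padded at sequence termini."""

    site_id: str
    window: str


@dataclass
class MotifConfig:
    flank: int = 10
    min_count: int = 21          # "more than 20" matching windows
    p_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError("flank must be >= 1")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass
class Motif:
    """A fixed set of (offset, residue) constraints around the central K."""

    constraints: dict[int, str]
    count: int
    p_values: dict[int, float]
    flank: int = 10

    @property
    def consensus(self) -> str:
        chars = []
        for offset in range(-self.flank, self.flank + 1):
            if offset == 0:
                chars.append("K")
            else:
                chars.append(self.constraints.get(offset, "."))
        return "".join(chars)


def sites_per_protein(sites: Iterable[SiteRecord]) -> dict[int, int]:
    """Histogram {number of sites on a protein → number of such proteins}."""
    sites = list(sites)
    if not sites:
        raise ValueError("no sites given")
    per_protein = Counter(s.protein for s in sites)
    hist: Counter[int] = Counter(per_protein.values())
    return dict(sorted(hist.items()))


def _window_at(sequence: str, position: int, flank: int) -> str:
    start = position - 1 - flank
    end = position + flank
    left_pad = max(0, -start)
    right_pad = max(0, end - len(sequence))
    return PAD * left_pad + sequence[max(0, start) : min(end, len(sequence))] + PAD * right_pad


def extract_windows(
    sites: Iterable[SiteRecord], sequences: Mapping[str, str], flank: int = 10
) -> list[SiteWindow]:
    """One window per site; errors if a site does not point at a K."""
    windows = []
    for site in sites:
        if site.protein not in sequences:
            raise KeyError(f"no sequence for {site.protein!r}")
        seq = sequences[site.protein]
        if not 1 <= site.position <= len(seq):
            raise IndexError(
                f"site {site.site_id}: position {site.position} outside "
                f"1..{len(seq)}"
            )
        if seq[site.position - 1] != "K":
            raise ValueError(
                f"site {site.site_id}: residue at position {site.position} is "
                f"{seq[site.position - 1]!r}, not 'K'"
            )
        windows.append(SiteWindow(site.site_id, _window_at(seq, site.position, flank)))
    return windows


def background_windows(
    sequences: Mapping[str, str], flank: int = 10
) -> list[SiteWindow]:
    """One window per lysine in the proteome — all potential modification sites."""
    windows = []
    for acc, seq in sequences.items():
        for idx, residue in enumerate(seq):
            if residue == "K":
                pos = idx + 1
                windows.append(SiteWindow(f"{acc}:K{pos}", _window_at(seq, pos, flank)))
    if not windows:
        warnings.warn("proteome contains no lysines; background is empty", stacklevel=2)
    return windows


def _position_counts(
    windows: Sequence[SiteWindow], flank: int
) -> tuple[np.ndarray, np.ndarray]:
    """Counts[residue, position] over non-pad characters, and per-position
    non-pad totals.  Pad characters never enter a denominator."""
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    counts = np.zeros((len(STANDARD_AA), 2 * flank + 1), dtype=np.int64)
    for w in windows:
        if len(w.window) != 2 * flank + 1:
            raise ValueError(f"window {w.site_id} has length {len(w.window)}")
        for col, ch in enumerate(w.window):
            if ch != PAD:
                counts[aa_index[ch], col] += 1
    return counts, counts.sum(axis=0)


@dataclass
class PositionFrequencyMatrix:
    """20 residues × (2·flank+1) positions: foreground frequency, background
    frequency, smoothed log2 ratio, and one-sided binomial enrichment p."""

    fg_freq: pd.DataFrame
    bg_freq: pd.DataFrame
    log2_ratio: pd.DataFrame
    p_value: pd.DataFrame
    flank: int = 10

    def to_long(self) -> pd.DataFrame:
        frames = []
        for name, df in (
            ("fg_freq", self.fg_freq),
            ("bg_freq", self.bg_freq),
            ("log2_ratio", self.log2_ratio),
            ("p_value", self.p_value),
        ):
            long = df.stack().rename(name)
            frames.append(long)
        out = pd.concat(frames, axis=1).reset_index()
        out.columns = ["residue", "offset", "fg_freq", "bg_freq", "log2_ratio", "p_value"]
        return out


def position_frequency(
    fg: Sequence[SiteWindow], bg: Sequence[SiteWindow], flank: int = 10
) -> PositionFrequencyMatrix:
    """Per (residue, offset) foreground/background frequencies and enrichment.

    The log2 ratio uses 0.5-count additive smoothing in both numerator and
    denominator; the binomial test is unsmoothed: P(X ≥ k) for k foreground
    occurrences among n non-pad foreground characters at background rate q.
    """
    if not fg or not bg:
        raise ValueError("foreground and background must be nonempty")
    fg_counts, fg_totals = _position_counts(fg, flank)
    bg_counts, bg_totals = _position_counts(bg, flank)
    with np.errstate(invalid="ignore", divide="ignore"):
        fg_freq = np.where(fg_totals > 0, fg_counts / fg_totals, 0.0)
        bg_freq = np.where(bg_totals > 0, bg_counts / bg_totals, 0.0)
        smoothed_fg = (fg_counts + 0.5) / (fg_totals + 0.5 * len(STANDARD_AA))
        smoothed_bg = (bg_counts + 0.5) / (bg_totals + 0.5 * len(STANDARD_AA))
        log2_ratio = np.log2(smoothed_fg / smoothed_bg)
    p = np.ones_like(fg_freq)
    for col in range(fg_counts.shape[1]):
        n = int(fg_totals[col])
        if n == 0:
            continue
        for row in range(fg_counts.shape[0]):
            q = bg_freq[row, col]
            k = int(fg_counts[row, col])
            p[row, col] = stats.binom.sf(k - 1, n, q) if k > 0 else 1.0
    offsets = list(range(-flank, flank + 1))
    residues = list(STANDARD_AA)
    as_df = lambda a: pd.DataFrame(a, index=residues, columns=offsets)  # noqa: E731
    return PositionFrequencyMatrix(
        fg_freq=as_df(fg_freq),
        bg_freq=as_df(bg_freq),
        log2_ratio=as_df(log2_ratio),
        p_value=as_df(p),
        flank=flank,
    )


def _binomial_p(k: int, n: int, q: float) -> float:
    return float(stats.binom.sf(k - 1, n, q)) if k > 0 else 1.0


def motif_discovery(
    fg: Sequence[SiteWindow], bg: Sequence[SiteWindow], config: MotifConfig | None = None
) -> list[Motif]:
    """Greedy motif-x-style extraction; an empty list is a valid outcome.

    Loop: among unfixed (residue, offset≠0) cells, compute the one-sided
    binomial p of the residue count at that offset in the remaining
    foreground against the full-background rate; pick the smallest p (ties:
    alphabetical residue, then offset closest to the center); fix the cell
    only if p < p_threshold and at least ``min_count`` windows match; recurse
    on matching windows.  When no cell qualifies, the accumulated constraints
    (if any) become a motif, its matching windows are removed, and the search
    restarts on the remainder.
    """
    config = config or MotifConfig()
    if not fg or not bg:
        raise ValueError("foreground and background must be nonempty")
    flank = config.flank
    bg_counts, bg_totals = _position_counts(bg, flank)
    with np.errstate(invalid="ignore", divide="ignore"):
        bg_freq = np.where(bg_totals > 0, bg_counts / bg_totals, 0.0)
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}

    remaining = [w.window for w in fg]
    motifs: list[Motif] = []
    while True:
        constraints: dict[int, str] = {}
        p_values: dict[int, float] = {}
        current = list(remaining)
        while True:
            best = None
            for offset in range(-flank, flank + 1):
                if offset == 0 or offset in constraints:
                    continue
                col = offset + flank
                chars = [w[col] for w in current if w[col] != PAD]
                n = len(chars)
                if n < config.min_count:
                    continue
                counter = Counter(chars)
                for residue in sorted(counter):
                    k = counter[residue]
                    if k < config.min_count:
                        continue
                    p = _binomial_p(k, n, bg_freq[aa_index[residue], col])
                    if p >= config.p_threshold:
                        continue
                    key = (p, residue, abs(offset), offset)
                    if best is None or key < best[0]:
                        best = (key, offset, residue, p)
            if best is None:
                break
            _, offset, residue, p = best
            constraints[offset] = residue
            p_values[offset] = p
            col = offset + flank
            current = [w for w in current if w[col] == residue]
        if not constraints:
            break
        motifs.append(
            Motif(constraints=constraints, count=len(current), p_values=p_values, flank=flank)
        )
        remaining = [
            w
            for w in remaining
            if not all(w[o + flank] == r for o, r in constraints.items())
        ]
        if not remaining:
            break
    return motifs
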