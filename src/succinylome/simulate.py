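"""Synthetic succinylome generator with known ground truth.

Emulates the design of a two-condition label-free experiment — two groups
(control "0h", treated "8h") of three biological replicates — at the level
the pipeline consumes: protein sequences, succinylated lysine positions, and
a peptide/site intensity matrix.  Intensities are multiplicative:

    I_ij = base_j · fc_j^[sample i treated] · scaling_i · noise_ij

with per-site base intensities drawn log-uniform over a wide LC–MS dynamic
range, per-sample global scaling factors (what median normalization must
remove), mean-one log-normal noise of configurable coefficient of variation,
and missing-completely-at-random dropout (optionally intensity-dependent).
Every random draw comes from explicitly seeded generators; no global RNG
state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import IntensityMatrix, SampleSheet, SiteRecord

# Average amino-acid frequencies of the UniProtKB/Swiss-Prot database,
# normalized; lysine sits near 5.8%, which sets how many candidate sites a
# random protein offers.
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array(
    [
        8.25, 1.38, 5.46, 6.72, 3.86, 7.08, 2.27, 5.91, 5.80, 9.65,
        2.41, 4.06, 4.74, 3.93, 5.53, 6.63, 5.35, 6.86, 1.10, 2.92,
    ]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


def _default_sites_dist() -> dict[int, float]:
    """Default sites-per-protein distribution.

    Mirrors the published succinylome shape: 17.2% / 9.4% / 6.6% / 3.9% of
    proteins with 2/3/4/5 sites, 15 of 256 proteins with more than five
    (spread evenly over 6..13), and the remaining mass (≈0.570) on
    single-site proteins.
    """
    dist = {2: 0.172, 3: 0.094, 4: 0.066, 5: 0.039}
    heavy = 15.0 / 256.0
    for k in range(6, 14):
        dist[k] = heavy / 8.0
    dist[1] = 1.0 - sum(dist.values())
    return dict(sorted(dist.items()))


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the synthetic succinylome."""

    n_proteins: int = 300
    protein_length: tuple[int, int] = (80, 600)
    sites_per_protein_dist: dict[int, float] = field(default_factory=_default_sites_dist)
    n_replicates_per_group: int = 3
    groups: tuple[str, str] = ("0h", "8h")
    true_fc_map: dict[str, float] = field(default_factory=dict)
    noise_cv: float = 0.1
    sample_scaling: Sequence[float] | None = None
    missing_rate: float = 0.05
    mnar: bool = False
    base_intensity_range: tuple[float, float] = (1e5, 1e9)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.sites_per_protein_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sites_per_protein_dist sums to {total}, not 1")
        if any(k < 1 for k in self.sites_per_protein_dist):
            raise ValueError("site counts must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.protein_length
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid protein_length range ({lo}, {hi})")
        if self.n_replicates_per_group < 1:
            raise ValueError("need at least one replicate per group")
        if self.sample_scaling is not None:
            if len(self.sample_scaling) != self.n_samples:
                raise ValueError(
                    f"sample_scaling needs {self.n_samples} factors, "
                    f"got {len(self.sample_scaling)}"
                )
            if any(s <= 0 for s in self.sample_scaling):
                raise ValueError("scaling factors must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.groups) * self.n_replicates_per_group

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{g}_r{r}"
            for g in self.groups
            for r in range(1, self.n_replicates_per_group + 1)
        ]


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    fold_changes: dict[str, float]
    site_map: dict[str, tuple[str, int]]
    sample_scaling: dict[str, float]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # Independent deterministic streams per generation stage; the proteome
    # and site stages must agree on per-protein site counts, so both derive
    # them from stream 0.
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _draw_site_counts(config: SimulationConfig) -> np.ndarray:
    rng = _rng(config, 0)
    counts = np.array(list(config.sites_per_protein_dist))
    probs = np.array(list(config.sites_per_protein_dist.values()))
    return rng.choice(counts, size=config.n_proteins, p=probs)


def generate_proteome(config: SimulationConfig, max_retries: int = 100) -> dict[str, str]:
    """Random protein sequences with enough lysines for their assigned sites.

    Each protein's sequence is redrawn (length included) until it carries at
    least as many K residues as the sites it will be assigned; a protein that
    fails after ``max_retries`` attempts raises.
    """
    site_counts = _draw_site_counts(config)
    rng = _rng(config, 1)
    lo, hi = config.protein_length
    residues = np.array(list(_AA))
    proteome: dict[str, str] = {}
    for idx, need_k in enumerate(site_counts):
        acc = f"SYN{idx + 1:05d}"
        for attempt in range(max_retries):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(residues, size=length, p=_AA_FREQ))
            if seq.count("K") >= need_k:
                proteome[acc] = seq
                break
        else:
            raise RuntimeError(
                f"could not place {need_k} sites on {acc} after {max_retries} "
                f"attempts; widen protein_length or lower the site count"
            )
    return proteome


def generate_sites(
    proteome: Mapping[str, str], config: SimulationConfig
) -> list[SiteRecord]:
    """Assign succinylated positions: per protein, its drawn number of
    distinct K residues, chosen uniformly without replacement."""
    if not proteome:
        raise ValueError("proteome is empty")
    site_counts = _draw_site_counts(config)
    rng = _rng(config, 2)
    sites: list[SiteRecord] = []
    for (acc, seq), count in zip(proteome.items(), site_counts):
        k_positions = np.array([i + 1 for i, aa in enumerate(seq) if aa == "K"])
        chosen = rng.choice(k_positions, size=int(count), replace=False)
        sites.extend(SiteRecord(acc, int(pos)) for pos in sorted(chosen))
    return sites


def spike_fold_changes(
    sites: Sequence[SiteRecord],
    n_spiked: int,
    fc: float,
    config: SimulationConfig,
) -> dict[str, float]:
    """Pick ``n_spiked`` sites (deterministically under the config seed) and
    assign them the true fold change ``fc``; all other sites stay at 1."""
    if n_spiked > len(sites):
        raise ValueError(f"cannot spike {n_spiked} of {len(sites)} sites")
    rng = _rng(config, 3)
    chosen = rng.choice(len(sites), size=n_spiked, replace=False)
    return {sites[i].site_id: fc for i in chosen}


def generate_intensities(
    sites: Sequence[SiteRecord], config: SimulationConfig
) -> tuple[IntensityMatrix, SampleSheet, GroundTruth]:
    """Emit the replicate intensity matrix plus the ground truth behind it."""
    if not sites:
        raise ValueError("no sites to quantify")
    if config.missing_rate >= 1.0:
        raise ValueError("missing_rate=1 leaves no quantifiable data")
    rng = _rng(config, 4)
    samples = config.sample_names
    treated = config.groups[-1]
    is_treated = np.array([name.rsplit("_r", 1)[0] == treated for name in samples])

    if config.sample_scaling is not None:
        scaling = np.asarray(config.sample_scaling, dtype=float)
    else:
        # Global loading/instrument factors within a 4-fold span.
        scaling = np.exp(rng.uniform(math.log(0.5), math.log(2.0), size=len(samples)))

    n = len(sites)
    lo, hi = config.base_intensity_range
    base = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    fcs = np.array([config.true_fc_map.get(s.site_id, 1.0) for s in sites])

    intensity = base[:, None] * np.where(is_treated[None, :], fcs[:, None], 1.0)
    intensity = intensity * scaling[None, :]
    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=intensity.shape)
        intensity = intensity * noise

    if config.missing_rate > 0:
        if config.mnar:
            # Intensity-dependent dropout: rank-based, low signals drop first,
            # overall rate preserved.
            ranks = intensity.argsort(axis=None).argsort(axis=None).reshape(intensity.shape)
            prob = 2.0 * config.missing_rate * (1.0 - ranks / (intensity.size - 1))
            prob = np.clip(prob, 0.0, 1.0)
        else:
            prob = np.full(intensity.shape, config.missing_rate)
        dropout = rng.random(size=intensity.shape) < prob
        intensity = np.where(dropout, np.nan, intensity)

    ids = [s.site_id for s in sites]
    values = pd.DataFrame(intensity, index=ids, columns=samples)
    features = pd.DataFrame(
        {"protein": [s.protein for s in sites], "position": [s.position for s in sites]},
        index=ids,
    )
    sheet = SampleSheet(
        {
            name: (name.rsplit("_r", 1)[0], int(name.rsplit("_r", 1)[1]))
            for name in samples
        }
    )
    truth = GroundTruth(
        fold_changes={s.site_id: config.true_fc_map.get(s.site_id, 1.0) for s in sites},
        site_map={s.site_id: (s.protein, s.position) for s in sites},
        sample_scaling=dict(zip(samples, scaling.tolist())),
    )
    return IntensityMatrix(values=values, features=features), sheet, truth


@dataclass
class SyntheticDataset:
    proteome: dict[str, str]
    sites: list[SiteRecord]
    intensities: IntensityMatrix
    sample_sheet: SampleSheet
    truth: GroundTruth
    config: SimulationConfig


def simulate_experiment(
    config: SimulationConfig,
    n_spiked: int = 0,
    spike_fc: float = 2.0,
) -> SyntheticDataset:
    """One-call simulation: proteome → sites → (optional spikes) → intensities."""
    proteome = generate_proteome(config)
    sites = generate_sites(proteome, config)
    if n_spiked:
        spikes = spike_fold_changes(sites, n_spiked, spike_fc, config)
        config = replace(config, true_fc_map={**config.true_fc_map, **spikes})
    matrix, sheet, truth = generate_intensities(sites, config)
    return SyntheticDataset(proteome, sites, matrix, sheet, truth, config)
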