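"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The count generator emulates a small-RNA-seq experiment of a melanoma cell
line under two exposures: negative-binomial counts (variance mu + alpha mu^2),
3 replicates per condition by default, log-normal library-size variation,
planted log2 fold-change effects per condition, and planted co-expression
clusters driven by one latent log-normal factor per cluster — the structure
the mutual-information network stage is meant to recover.

Ground truth (cluster membership and planted effects) is returned alongside
the matrix so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountMatrix

DEFAULT_GROUPS = ("control", "LTyr", "BrdU")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic small-RNA-seq experiment.

    clusters: list of (member_indices, loading) — members share one latent
    standard-normal factor per sample, entering the NB mean as
    2^(loading * z).  de_effects: miRNA index -> (condition, log2 fold
    change) applied to that condition's samples.
    """

    n_mirnas: int = 200
    n_samples_per_group: int = 3
    groups: tuple[str, ...] = DEFAULT_GROUPS
    clusters: list[tuple[list[int], float]] = field(default_factory=list)
    de_effects: dict[int, tuple[str, float]] = field(default_factory=dict)
    base_mean_range: tuple[float, float] = (20.0, 2000.0)
    dispersion: float = 0.1
    libsize_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_samples_per_group < 1:
            raise ConfigurationError("n_mirnas and n_samples_per_group must be >= 1")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")
        if self.libsize_cv < 0:
            raise ConfigurationError("libsize_cv must be non-negative")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise ConfigurationError("base_mean_range must be positive and ordered")
        seen: set[int] = set()
        for members, loading in self.clusters:
            if not np.isfinite(loading):
                raise ConfigurationError("cluster loading must be finite")
            for idx in members:
                if idx in seen:
                    raise ConfigurationError(
                        f"miRNA index {idx} appears in more than one cluster"
                    )
                if not 0 <= idx < self.n_mirnas:
                    raise ConfigurationError(f"cluster index {idx} out of range")
                seen.add(idx)
        for idx, (cond, _lfc) in self.de_effects.items():
            if not 0 <= idx < self.n_mirnas:
                raise ConfigurationError(f"DE index {idx} out of range")
            if cond not in self.groups:
                raise ConfigurationError(f"DE condition {cond!r} not in groups")


@dataclass
class SyntheticTruth:
    """Planted structure: cluster membership, true log2 fold changes, and the
    library-size factors the counts were scaled by."""

    cluster_membership: dict[str, int]
    de_flags: dict[tuple[str, str], float]
    size_factors: dict[str, float] = field(default_factory=dict)

    def members_of(self, cluster_id: int) -> set:
        return {m for m, c in self.cluster_membership.items() if c == cluster_id}

    def to_json(self, path) -> None:
        payload = {
            "cluster_membership": self.cluster_membership,
            "de_flags": [
                {"mirna_id": m, "condition": c, "log2fc": v}
                for (m, c), v in self.de_flags.items()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, alpha) with variance mean + alpha mean^2; Poisson at alpha ~ 0."""
    if alpha < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / alpha  # numpy's n parameter
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(cfg: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one synthetic count matrix and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n_g = cfg.n_mirnas
    sample_ids, group_of = [], {}
    for g in cfg.groups:
        for r in range(cfg.n_samples_per_group):
            sid = f"{g}_{r + 1}"
            sample_ids.append(sid)
            group_of[sid] = g
    n_s = len(sample_ids)
    mirna_ids = [f"mmu-mir-sim-{i:04d}" for i in range(n_g)]

    lo, hi = cfg.base_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_g))

    if cfg.libsize_cv > 0:
        sigma2 = np.log1p(cfg.libsize_cv**2)
        size_factor = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n_s)
    else:
        size_factor = np.ones(n_s)

    log2_effect = np.zeros((n_g, n_s))
    for ci, (members, loading) in enumerate(cfg.clusters):
        z = rng.standard_normal(n_s)
        for idx in members:
            log2_effect[idx] += loading * z
    for idx, (cond, lfc) in cfg.de_effects.items():
        in_cond = np.array([group_of[s] == cond for s in sample_ids])
        log2_effect[idx, in_cond] += lfc

    mean = size_factor[None, :] * base_mean[:, None] * 2.0**log2_effect
    counts = _nb_draw(rng, mean, cfg.dispersion)

    cm = CountMatrix(
        pd.DataFrame(counts, index=mirna_ids, columns=sample_ids), group_of
    )
    membership = {
        mirna_ids[idx]: ci
        for ci, (members, _l) in enumerate(cfg.clusters)
        for idx in members
    }
    de_flags = {
        (mirna_ids[idx], cond): lfc for idx, (cond, lfc) in cfg.de_effects.items()
    }
    return cm, SyntheticTruth(
        cluster_membership=membership,
        de_flags=de_flags,
        size_factors=dict(zip(sample_ids, size_factor.tolist())),
    )


def simulate_qpcr(
    true_ratios: dict[str, float],
    efficiencies: dict[str, float] | float = 2.0,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    reference_id: str = "U6",
    treated_condition: str = "treated",
) -> pd.DataFrame:
    """Long-format qPCR table whose noiseless rER recovers ``true_ratios``.

    The reference gene gets identical Ct in control and treated (dCt_ref = 0);
    each target's treated Ct is offset so that
    E_target^(Ct_control - Ct_treated) equals the requested ratio exactly.
    Gaussian noise of sd ``ct_noise_sd`` is added per replicate Ct.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    def eff(name: str) -> float:
        e = efficiencies if isinstance(efficiencies, (int, float)) else (
            efficiencies.get(name, 2.0)
        )
        if not (1.0 < e <= 2.2):
            raise ValueError(f"efficiency for {name!r} must lie in (1, 2.2]; got {e}")
        return float(e)

    rows = []

    def emit(gene, cond, base_ct, e):
        for r in range(1, n_replicates + 1):
            noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows.append((gene, reference_id, cond, r, base_ct + noise, e))

    e_ref = eff(reference_id)
    emit(reference_id, "control", 20.0, e_ref)
    emit(reference_id, treated_condition, 20.0, e_ref)
    for gene, ratio in true_ratios.items():
        if ratio <= 0:
            raise ValueError("true ratios must be positive")
        e_t = eff(gene)
        ct_control = 25.0
        # rER = e_t^(ct_control - ct_treated) = ratio
        ct_treated = ct_control - np.log(ratio) / np.log(e_t)
        emit(gene, "control", ct_control, e_t)
        emit(gene, treated_condition, ct_treated, e_t)
    return pd.DataFrame(
        rows,
        columns=["target_id", "reference_id", "condition", "replicate", "Ct",
                 "efficiency"],
    )


def simulate_growth(
    n0: float,
    doubling_time_h: float,
    times_h,
    noise_cv: float = 0.0,
    seed: int = 0,
    condition: str = "control",
) -> pd.DataFrame:
    """Exponential growth observations n0 * 2^(t / Td) with multiplicative noise."""
    if n0 <= 0 or doubling_time_h <= 0:
        raise ValueError("n0 and doubling time must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.asarray(times_h, dtype=float)
    counts = n0 * 2.0 ** (times / doubling_time_h)
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        counts = counts * rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), len(times))
    return pd.DataFrame(
        {"time_h": times, "cell_count": counts, "condition": condition}
    )
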