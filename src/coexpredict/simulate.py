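"""Synthetic multi-strain time-course expression data with planted modules.

The generator emulates the structure of the challenge data — four yeast
strains (one wild type, three regulator-deletion strains), eight timepoints
after a chemical perturbation, two biological replicates, RMA-like log-scale
values — without attempting biological realism:

* genes are grouped into co-expression modules; each module has a smooth
  latent time profile per strain (a smoothed random walk, standardized to
  unit variance over time);
* a strain's latent profile is an affine perturbation of the wild-type
  profile (whole-module shifts/scalings, mimicking pathway-level effects of
  a regulator deletion); the prediction strain additionally receives a
  module-specific perturbation curve whose magnitude varies across modules;
* gene values are ``loading * latent + module baseline + gene offset``
  plus i.i.d. Gaussian noise per replicate; a fraction of background genes
  have independent profiles per strain;
* prediction targets are sampled preferentially from the most strongly
  perturbed modules (at most half of a module), mirroring the observation
  that real challenge targets were highly perturbed genes.

Absolute levels are shared at module level (modules differ by a baseline of
sd ~2 on the log2-like scale) with only a small per-gene offset, so that
co-expressed genes are informative about each other's absolute level — the
regime in which neighbor averaging is a sensible estimator.

Everything is drawn from a single seeded generator stream, so a config is
reproduced byte-for-byte from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ExpressionDataset, TargetSet

__all__ = ["SimConfig", "SimTruth", "generate", "make_fixture", "PRESETS"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic multi-strain time-course generator.

    Defaults reproduce the challenge-scale conditions: 6000 genes, 50
    targets, four strains, eight timepoints (minutes after perturbation),
    two replicates, noise sd one tenth of the unit latent signal sd.
    """

    n_genes: int = 6000
    n_targets: int = 50
    strains: tuple[str, ...] = ("wt", "gat1d", "gcn4d", "leu3d")
    prediction_strain: str = "gat1d"
    timepoints: tuple[float, ...] = (0, 10, 20, 30, 45, 60, 90, 120)
    n_replicates: int = 2
    module_size_range: tuple[int, int] = (8, 30)
    background_fraction: float = 0.2
    smoothing_window: int = 3  # moving-average window of the latent random walk
    baseline_mean: float = 7.0  # log2-like overall expression level
    module_baseline_sd: float = 2.0  # spread of absolute levels across modules
    gene_offset_sd: float = 0.3  # per-gene deviation from the module baseline
    loading_sd: float = 0.2  # per-gene deviation from unit loading
    strain_scale_sd: float = 0.2  # per-(module, strain) latent scaling spread
    strain_shift_sd: float = 0.3  # per-(module, strain) latent shift spread
    pred_perturbation: float = 0.8  # sd of prediction-strain perturbation magnitudes
    target_boost: bool = True  # draw targets from the most perturbed modules
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.n_targets < self.n_genes):
            raise ValueError("need 0 < n_targets < n_genes")
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ValueError("module sizes must be >= 2 and lo <= hi")
        if self.noise_sd < 0 or self.gene_offset_sd < 0 or self.loading_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.prediction_strain not in self.strains:
            raise ValueError("prediction_strain must be one of strains")


@dataclass
class SimTruth:
    """Ground truth of a generated dataset.

    ``gold`` holds the generated (pre-masking) prediction-strain values of
    the targets, exactly as drawn; ``gold_frame()`` gives the replicate mean
    used for scoring.
    """

    module_of_gene: pd.Series  # gene id -> module index (-1 = background)
    latent_profiles: dict  # (module, strain) -> latent curve
    perturbation: pd.Series  # module index -> prediction-strain perturbation size
    gold: np.ndarray  # (n_targets, n_timepoints, n_replicates)
    target_genes: tuple[str, ...]
    timepoints: tuple[float, ...]
    config: SimConfig = field(repr=False, default=None)

    def gold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.gold.mean(axis=2), index=list(self.target_genes), columns=list(self.timepoints)
        )


def _smooth_curve(rng: np.random.Generator, n: int, window: int) -> np.ndarray:
    """Unit-variance smoothed random walk over n timepoints."""
    for _ in range(100):
        walk = np.cumsum(rng.normal(size=n + window - 1))
        smoothed = np.convolve(walk, np.ones(window) / window, mode="valid")
        sd = smoothed.std()
        if sd > 1e-9:
            return (smoothed - smoothed.mean()) / sd
    raise RuntimeError("degenerate latent curve")  # pragma: no cover


def _draw_module_sizes(rng: np.random.Generator, cfg: SimConfig) -> list[int]:
    n_module_genes = round(cfg.n_genes * (1 - cfg.background_fraction))
    lo, hi = cfg.module_size_range
    sizes: list[int] = []
    while sum(sizes) < n_module_genes:
        sizes.append(int(rng.integers(lo, hi + 1)))
    excess = sum(sizes) - n_module_genes
    if excess and sizes[-1] - excess >= 2:
        sizes[-1] -= excess
    elif excess:
        sizes.pop()
    return sizes


def generate(cfg: SimConfig) -> tuple[ExpressionDataset, TargetSet, SimTruth]:
    """Generate a dataset (targets masked), the target set, and the truth."""
    rng = np.random.default_rng(cfg.seed)
    n_tp, n_rep = len(cfg.timepoints), cfg.n_replicates
    strains = cfg.strains
    pred_s = cfg.prediction_strain

    sizes = _draw_module_sizes(rng, cfg)
    n_module_genes = sum(sizes)
    n_bg = cfg.n_genes - n_module_genes

    # latent profiles per (module, strain)
    latents: dict[tuple[int, str], np.ndarray] = {}
    perturbation = np.zeros(len(sizes))
    for m in range(len(sizes)):
        base = _smooth_curve(rng, n_tp, cfg.smoothing_window)
        for s in strains:
            if s == strains[0]:
                curve = base.copy()
            else:
                a = 1.0 + rng.normal(0.0, cfg.strain_scale_sd)
                b = rng.normal(0.0, cfg.strain_shift_sd)
                curve = a * base + b
            if s == pred_s:
                p = abs(rng.normal(0.0, cfg.pred_perturbation))
                curve = curve + p * _smooth_curve(rng, n_tp, cfg.smoothing_window)
                perturbation[m] = p
            latents[(m, s)] = curve

    module_of = np.repeat(np.arange(len(sizes)), sizes)
    module_of = np.concatenate([module_of, -np.ones(n_bg, dtype=int)])

    module_baseline = cfg.baseline_mean + rng.normal(0.0, cfg.module_baseline_sd, len(sizes))
    loading = 1.0 + rng.normal(0.0, cfg.loading_sd, cfg.n_genes)
    offset = rng.normal(0.0, cfg.gene_offset_sd, cfg.n_genes)
    bg_baseline = cfg.baseline_mean + rng.normal(0.0, cfg.module_baseline_sd, n_bg)

    values = np.empty((cfg.n_genes, len(strains), n_tp, n_rep))
    for si, s in enumerate(strains):
        signal = np.empty((cfg.n_genes, n_tp))
        for g in range(n_module_genes):
            m = module_of[g]
            signal[g] = loading[g] * latents[(m, s)] + module_baseline[m] + offset[g]
        for b in range(n_bg):
            g = n_module_genes + b
            signal[g] = _smooth_curve(rng, n_tp, cfg.smoothing_window) + bg_baseline[b] + offset[g]
        noise = rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n_tp, n_rep)) if cfg.noise_sd > 0 else 0.0
        values[:, si] = signal[:, :, np.newaxis] + noise

    # shuffle gene order so modules are not contiguous blocks
    perm = rng.permutation(cfg.n_genes)
    values = values[perm]
    module_of = module_of[perm]
    width = len(str(cfg.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]

    # choose targets from the most perturbed modules (at most half a module)
    member_idx = {m: np.flatnonzero(module_of == m) for m in range(len(sizes))}
    if cfg.target_boost:
        module_order = np.argsort(-perturbation, kind="stable")
    else:
        module_order = rng.permutation(len(sizes))
    chosen: list[int] = []
    for m in module_order:
        if len(chosen) >= cfg.n_targets:
            break
        members = member_idx[int(m)]
        quota = min(len(members) // 2, cfg.n_targets - len(chosen))
        if quota > 0:
            picks = rng.choice(members, size=quota, replace=False)
            chosen.extend(int(i) for i in np.sort(picks))
    if len(chosen) < cfg.n_targets:
        raise ValueError(
            f"infeasible config: only {len(chosen)} target slots available "
            f"for n_targets={cfg.n_targets}"
        )
    chosen = sorted(chosen)
    target_genes = tuple(genes[i] for i in chosen)
    targets = TargetSet(target_genes, pred_s)

    pred_si = strains.index(pred_s)
    gold = values[chosen, pred_si].copy()

    ds = ExpressionDataset(genes, strains, pred_s, cfg.timepoints, values)
    ds = ds.mask_targets(targets)
    truth = SimTruth(
        module_of_gene=pd.Series(module_of, index=genes),
        latent_profiles=latents,
        perturbation=pd.Series(perturbation),
        gold=gold,
        target_genes=target_genes,
        timepoints=cfg.timepoints,
        config=cfg,
    )
    return ds, targets, truth


PRESETS: dict[str, SimConfig] = {
    # small instance for oracle-style tests
    "tiny": SimConfig(
        n_genes=30,
        n_targets=3,
        module_size_range=(4, 8),
        background_fraction=0.2,
        n_replicates=2,
    ),
    # challenge-scale instance: 6000 genes x 4 strains x 8 timepoints x 2 reps
    "dream-like": SimConfig(),
    # heterogeneous module sizes, mid-scale: the regime where adaptive
    # neighborhoods (mutual KNN) should beat a fixed k
    "hetero-small": SimConfig(
        n_genes=400,
        n_targets=20,
        module_size_range=(3, 30),
        background_fraction=0.15,
    ),
}


def make_fixture(name: str, seed: int | None = None):
    """Generate a named preset; ``seed`` overrides the preset's pinned seed."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return generate(cfg)
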