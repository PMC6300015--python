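"""Synthetic hashed-droplet experiments with known ground truth.

Droplet occupancy follows Poisson loading: the number of true cells in a
droplet is Poisson(``lambda_cells``). Under "super-loading" the instrument is
run well above the usual concentration, accepting an elevated multiplet rate
because cross-sample multiplets — droplets whose member cells carry different
hashtags — are detectable and discardable. Only same-sample multiplets remain
unresolved. :func:`expected_loading_stats` gives the closed-form fractions;
:func:`simulate_experiment` draws a full experiment (HTO count matrix plus
per-droplet ground truth) from the loading and signal models.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import TagCountMatrix

__all__ = [
    "LoadingModel",
    "SignalModel",
    "expected_loading_stats",
    "simulate_experiment",
    "sample_names",
    "load_sim_config",
]

#: Droplet ground-truth classes.
EMPTY = "empty"
SINGLET = "singlet"
MULTIPLET = "multiplet"
NEGATIVE_CONTROL = "negative-control-only"


def sample_names(s: int) -> list[str]:
    """Default sample names: single letters A.. for s <= 26, else S1..Ss."""
    if s <= 26:
        return list(string.ascii_uppercase[:s])
    return [f"S{i + 1}" for i in range(s)]


@dataclass(frozen=True)
class LoadingModel:
    """Poisson droplet-loading model.

    Defaults reproduce a super-loaded run with an expected 4:1
    singlet:multiplet yield (20,000 singlets per 5,000 multiplets implies
    (e^λ − 1 − λ)/λ = 1/4, i.e. λ ≈ 0.43) across eight equally pooled
    samples, with a tenth of cells left unstained as negative controls.

    Attributes
    ----------
    lambda_cells : float
        Mean true cells per droplet (Poisson rate).
    sample_proportions : tuple of float
        Mixing fractions of the pooled samples; must sum to 1.
    n_droplets : int
        Number of droplets to emit (including empty ones).
    unlabeled_fraction : float
        Fraction in [0, 1) of cells carrying no hashtag (unstained
        negative-control cells).
    """

    lambda_cells: float = 0.43
    sample_proportions: tuple = tuple([1.0 / 8] * 8)
    n_droplets: int = 20_000
    unlabeled_fraction: float = 0.1

    def __post_init__(self):
        p = np.asarray(self.sample_proportions, dtype=float)
        if self.lambda_cells <= 0:
            raise ValueError("lambda_cells must be > 0")
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if p.ndim != 1 or len(p) < 1:
            raise ValueError("sample_proportions must be a non-empty vector")
        if (p < 0).any():
            raise ValueError("sample_proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"sample_proportions must sum to 1 (got {p.sum():.15g})"
            )
        if not 0 <= self.unlabeled_fraction < 1:
            raise ValueError("unlabeled_fraction must be in [0, 1)")
        object.__setattr__(self, "sample_proportions", tuple(float(x) for x in p))

    @property
    def n_samples(self) -> int:
        return len(self.sample_proportions)


@dataclass(frozen=True)
class SignalModel:
    """Per-cell hashtag signal and background count model.

    A droplet's count for tag t is NB(signal_mean · m_t, signal_dispersion)
    + NB(background_mean, background_dispersion), where m_t is the number of
    member cells labeled t (zero signal term when m_t = 0). Negative
    binomials are parameterized by (mean, size); size → ∞ recovers Poisson.
    RNA UMI totals per cell are lognormal and are summed per droplet; they
    only exercise the 200-UMI inclusion and 50–200-UMI rescue gates.
    """

    signal_mean: float = 100.0
    signal_dispersion: float = 5.0
    background_mean: float = 2.0
    background_dispersion: float = 2.0
    rna_umi_lognormal_params: tuple = (math.log(2000.0), 0.9)

    def __post_init__(self):
        if self.signal_mean < 0 or self.background_mean < 0:
            raise ValueError("NB means must be >= 0")
        if self.signal_dispersion <= 0 or self.background_dispersion <= 0:
            raise ValueError("NB dispersions (sizes) must be > 0")
        if self.signal_mean <= self.background_mean:
            raise ValueError("signal_mean must exceed background_mean")


def expected_loading_stats(lambda_cells: float, s: int, proportions) -> dict:
    """Closed-form droplet class fractions under truncated Poisson loading.

    All fractions are conditional on droplet occupancy >= 1. A multiplet is
    "unresolved" iff all member cells carry the same sample label (probability
    Σ_j p_j^k for a size-k droplet); otherwise it is a detectable
    cross-sample multiplet.

    Uses the probability generating function of the Poisson:
    Σ_{k≥2} e^{-λ} λ^k p^k / k! = e^{-λ} (e^{λp} − 1 − λp).

    Returns
    -------
    dict with keys ``frac_singlet``, ``frac_multiplet``,
    ``frac_cross_sample_multiplet``, ``frac_unresolved_multiplet``.
    """
    lam = float(lambda_cells)
    if lam <= 0:
        raise ValueError("lambda_cells must be > 0")
    p = np.asarray(proportions, dtype=float)
    if len(p) != s:
        raise ValueError(f"proportions has length {len(p)}, expected s={s}")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("proportions must be non-negative and sum to 1")

    z = -np.expm1(-lam)  # P(occupancy >= 1) = 1 - e^-lam
    frac_singlet = lam * math.exp(-lam) / z
    frac_multiplet = (1.0 - math.exp(-lam) * (1.0 + lam)) / z
    if s == 1:
        # one sample: every multiplet is same-sample, exactly
        unresolved, cross = frac_multiplet, 0.0
    else:
        # P(occupancy k >= 2, all k cells share one label)
        unresolved = math.exp(-lam) * np.sum(np.expm1(lam * p) - lam * p) / z
        cross = frac_multiplet - unresolved
    return {
        "frac_singlet": frac_singlet,
        "frac_multiplet": frac_multiplet,
        "frac_cross_sample_multiplet": cross,
        "frac_unresolved_multiplet": unresolved,
    }


def _nb_draw(rng: np.random.Generator, mean, size) -> np.ndarray:
    """NB(mean, size) draws via gamma–Poisson mixture; size=inf ⇒ Poisson."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if np.isinf(size):
        out[pos] = rng.poisson(mean[pos])
    else:
        lam = rng.gamma(shape=size, scale=mean[pos] / size)
        out[pos] = rng.poisson(lam)
    return out


def _droplet_barcodes(rng: np.random.Generator, n: int, length: int = 16) -> np.ndarray:
    """Deterministic, collision-free random DNA barcodes."""
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out = np.empty(n, dtype=object)
    i = 0
    while i < n:
        bc = "".join(bases[rng.integers(0, 4, size=length)])
        if bc in seen:
            continue
        seen.add(bc)
        out[i] = bc
        i += 1
    return out


def simulate_experiment(
    loading: LoadingModel, signal: SignalModel, seed: int
) -> tuple[TagCountMatrix, pd.DataFrame]:
    """Simulate one hashed droplet experiment.

    Returns
    -------
    counts : TagCountMatrix
        One row per non-empty droplet (>= 1 cell), columns = sample names.
    truth : pandas.DataFrame
        One row per droplet (empty droplets included; they emit no matrix
        row). Columns: ``droplet_id``, ``true_class``, ``member_samples``
        ('+'-joined labels of the labeled member cells, sorted),
        ``n_unlabeled``, ``is_cross_sample``, ``rna_umi``.
    """
    rng = np.random.default_rng(seed)
    s = loading.n_samples
    names = sample_names(s)
    p = np.asarray(loading.sample_proportions)

    occupancy = rng.poisson(loading.lambda_cells, size=loading.n_droplets)
    droplet_ids = _droplet_barcodes(rng, loading.n_droplets)

    # Per-droplet label multiplicities (s columns) and unlabeled-cell counts.
    label_mult = np.zeros((loading.n_droplets, s), dtype=np.int64)
    n_unlabeled = np.zeros(loading.n_droplets, dtype=np.int64)
    total_cells = int(occupancy.sum())
    # Draw all cell attributes at once, then aggregate per droplet.
    unlabeled = rng.random(total_cells) < loading.unlabeled_fraction
    labels = rng.choice(s, size=total_cells, p=p)
    loc, sc = signal.rna_umi_lognormal_params
    cell_rna = rng.lognormal(mean=loc, sigma=sc, size=total_cells)

    drop_of_cell = np.repeat(np.arange(loading.n_droplets), occupancy)
    lab_mask = ~unlabeled
    np.add.at(label_mult, (drop_of_cell[lab_mask], labels[lab_mask]), 1)
    np.add.at(n_unlabeled, drop_of_cell[unlabeled], 1)
    rna_umi = np.zeros(loading.n_droplets)
    np.add.at(rna_umi, drop_of_cell, cell_rna)
    rna_umi = np.round(rna_umi).astype(np.int64)

    n_labeled = label_mult.sum(axis=1)
    true_class = np.full(loading.n_droplets, EMPTY, dtype=object)
    true_class[(occupancy > 0) & (n_labeled == 0)] = NEGATIVE_CONTROL
    true_class[n_labeled == 1] = SINGLET
    true_class[n_labeled >= 2] = MULTIPLET
    distinct = (label_mult > 0).sum(axis=1)
    is_cross = (n_labeled >= 2) & (distinct >= 2)

    member = [
        "+".join(
            n for n, m in zip(names, row) for _ in range(m)
        )
        for row in label_mult
    ]

    truth = pd.DataFrame(
        {
            "droplet_id": droplet_ids,
            "true_class": true_class,
            "member_samples": member,
            "n_unlabeled": n_unlabeled,
            "is_cross_sample": is_cross,
            "rna_umi": rna_umi,
        }
    )

    keep = occupancy > 0
    mult = label_mult[keep]
    counts = _nb_draw(rng, signal.signal_mean * mult, signal.signal_dispersion)
    counts += _nb_draw(
        rng,
        np.full(mult.shape, signal.background_mean),
        signal.background_dispersion,
    )
    matrix = TagCountMatrix(counts, droplet_ids[keep], names)
    return matrix, truth


def load_sim_config(path) -> tuple[LoadingModel, SignalModel]:
    """Read simulator configuration from a flat TOML key/value file.

    Recognized keys are the field names of :class:`LoadingModel` and
    :class:`SignalModel`; missing keys take the defaults.
    """
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    known_loading = {f for f in LoadingModel.__dataclass_fields__}
    known_signal = {f for f in SignalModel.__dataclass_fields__}
    unknown = set(cfg) - known_loading - known_signal
    if unknown:
        raise ValueError(f"unknown simulator config keys: {sorted(unknown)}")
    lkw = {k: v for k, v in cfg.items() if k in known_loading}
    skw = {k: v for k, v in cfg.items() if k in known_signal}
    if "sample_proportions" in lkw:
        lkw["sample_proportions"] = tuple(lkw["sample_proportions"])
    if "rna_umi_lognormal_params" in skw:
        skw["rna_umi_lognormal_params"] = tuple(skw["rna_umi_lognormal_params"])
    return LoadingModel(**lkw), SignalModel(**skw)
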