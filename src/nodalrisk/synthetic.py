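"""Seeded generators of synthetic expression cohorts with known ground truth.

No expression data are deposited with the clinical model, so every other
module is exercised against simulated cohorts that emulate the relevant
study designs: a two-class (node-negative / node-positive) cohort at a
stated prevalence, matched FFPE/FF preservation pairs with tunable
concordance, and independent TUR/cystectomy specimen groups with a tunable
location shift.

The noise model is multivariate Gaussian on the log scale with a single
equicorrelation parameter across probes — the simplest structure that
exercises rank-correlation behaviour. Node-positive samples are shifted by
``effect_size`` on the first ``n_informative`` probes. FFPE/FF pairs share
a latent signal plus independent preservation noise calibrated so the
population correlation per probe equals ``pair_concordance``. One master
seed drives everything; per-generator streams are spawned deterministically
from it, so composite fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from nodalrisk.io import ExpressionMatrix, GenePanel

__all__ = [
    "SimulationConfig",
    "make_panel",
    "generate_cohort",
    "generate_matched_pairs",
    "generate_specimen_sets",
]

# typical log2 MAS5/RMA intensity of an expressed transcript
_BASELINE_MEAN = 8.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-cohort generators.

    n_samples : cohort size (or number of matched pairs).
    prevalence : probability a sample is node-positive (default 0.23,
        the baseline prevalence at radical cystectomy).
    n_probes : panel width (default 21, the clinical signature size).
    n_informative : probes carrying class signal (must be <= n_probes).
    effect_size : mean log-expression shift of informative probes in
        node-positive samples, in the same log units as noise_sd.
    within_class_correlation : equicorrelation of the Gaussian noise
        across probes, in [0, 1).
    noise_sd : standard deviation of per-probe noise (log units).
    pair_concordance : population FFPE-FF correlation per probe, in [-1, 1].
    specimen_shift : TUR-vs-cystectomy offset applied to informative probes.
    seed : master seed; all streams derive from it.
    """

    n_samples: int = 100
    prevalence: float = 0.23
    n_probes: int = 21
    n_informative: int = 10
    effect_size: float = 1.0
    within_class_correlation: float = 0.2
    noise_sd: float = 1.0
    pair_concordance: float = 0.8
    specimen_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if not 0 <= self.n_informative <= self.n_probes:
            raise ValueError("n_informative must be in [0, n_probes]")
        if not 0 <= self.within_class_correlation < 1:
            raise ValueError("within_class_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not -1 <= self.pair_concordance <= 1:
            raise ValueError("pair_concordance must be in [-1, 1]")


_STREAM_TAGS = {"cohort": 1, "pairs": 2, "specimens": 3}


def _streams(config: SimulationConfig, n: int, tag: str) -> list[np.random.Generator]:
    # distinct entropy per generator so composite fixtures built from one
    # master seed do not share noise
    seq = np.random.SeedSequence([config.seed, _STREAM_TAGS[tag]])
    return [np.random.Generator(np.random.PCG64(s)) for s in seq.spawn(n)]


def _probe_ids(n: int) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(n)]


def _equicorrelated_noise(
    rng: np.random.Generator, n_samples: int, n_probes: int, rho: float, sd: float
) -> np.ndarray:
    shared = rng.standard_normal((n_samples, 1))
    indep = rng.standard_normal((n_samples, n_probes))
    return sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * indep)


def make_panel(n_probes: int = 21, n_genes: int = 20) -> GenePanel:
    """A synthetic gene panel: probes assigned to genes round-robin.

    Defaults mirror the clinical signature's shape: 21 probes over 20
    distinct genes (one gene measured by two probes).
    """
    if not 1 <= n_genes <= n_probes:
        raise ValueError("need 1 <= n_genes <= n_probes")
    genes = [f"GENE{(i % n_genes) + 1}" for i in range(n_probes)]
    return GenePanel(entries=tuple(zip(_probe_ids(n_probes), genes)))


def generate_cohort(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.Series]:
    """A two-class expression cohort with known informative probes.

    Labels are Bernoulli(prevalence); node-positive samples get a mean
    shift of ``effect_size`` on the first ``n_informative`` probes.
    Returns the samples × probes matrix and the 0/1 label Series.
    """
    rng_labels, rng_noise = _streams(config, 2, "cohort")
    y = (rng_labels.random(config.n_samples) < config.prevalence).astype(int)
    noise = _equicorrelated_noise(
        rng_noise,
        config.n_samples,
        config.n_probes,
        config.within_class_correlation,
        config.noise_sd,
    )
    mean = np.full(config.n_probes, _BASELINE_MEAN)
    values = mean + noise
    values[y == 1, : config.n_informative] += config.effect_size
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=_probe_ids(config.n_probes))
    )
    labels = pd.Series(y, index=sample_ids, name="node_status")
    return matrix, labels


def generate_matched_pairs(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Matched FFPE and FF matrices with per-probe pair correlation.

    Each probe's FFPE and FF values share a latent component of variance
    ``|pair_concordance|`` plus independent noise, giving population
    correlation ``pair_concordance`` across pairs (negated latent loading
    for negative concordance). Sample IDs match one-to-one.
    """
    rng_latent, rng_ffpe, rng_ff = _streams(config, 3, "pairs")
    n, p = config.n_samples, config.n_probes
    rho = config.pair_concordance
    a = np.sqrt(abs(rho))
    b = np.sqrt(1 - abs(rho))
    latent = rng_latent.standard_normal((n, p))
    ffpe_vals = _BASELINE_MEAN + config.noise_sd * (
        a * latent + b * rng_ffpe.standard_normal((n, p))
    )
    sign = 1.0 if rho >= 0 else -1.0
    ff_vals = _BASELINE_MEAN + config.noise_sd * (
        sign * a * latent + b * rng_ff.standard_normal((n, p))
    )
    sample_ids = [f"PAIR{i + 1:04d}" for i in range(n)]
    probe_ids = _probe_ids(p)
    ffpe = ExpressionMatrix(
        values=pd.DataFrame(ffpe_vals, index=sample_ids, columns=probe_ids),
        preservation=pd.Series("FFPE", index=sample_ids),
    )
    ff = ExpressionMatrix(
        values=pd.DataFrame(ff_vals, index=sample_ids, columns=probe_ids),
        preservation=pd.Series("FF", index=sample_ids),
    )
    return ffpe, ff


def generate_specimen_sets(
    config: SimulationConfig, n_tur: int = 30, n_cyst: int = 25
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Independent TUR and cystectomy groups, the latter offset by
    ``specimen_shift`` on the first ``n_informative`` probes.

    Group sizes default to the fidelity-screen design (30 TUR vs 25
    cystectomy specimens).
    """
    if n_tur < 2 or n_cyst < 2:
        raise ValueError("n_tur and n_cyst must each be >= 2")
    rng_tur, rng_cyst = _streams(config, 2, "specimens")
    p = config.n_probes
    tur_vals = _BASELINE_MEAN + config.noise_sd * rng_tur.standard_normal((n_tur, p))
    cyst_vals = _BASELINE_MEAN + config.noise_sd * rng_cyst.standard_normal((n_cyst, p))
    cyst_vals[:, : config.n_informative] += config.specimen_shift
    probe_ids = _probe_ids(p)
    tur_ids = [f"TUR{i + 1:03d}" for i in range(n_tur)]
    cyst_ids = [f"CYS{i + 1:03d}" for i in range(n_cyst)]
    tur = ExpressionMatrix(
        values=pd.DataFrame(tur_vals, index=tur_ids, columns=probe_ids),
        specimen_source=pd.Series("TUR", index=tur_ids),
    )
    cyst = ExpressionMatrix(
        values=pd.DataFrame(cyst_vals, index=cyst_ids, columns=probe_ids),
        specimen_source=pd.Series("cystectomy", index=cyst_ids),
    )
    return tur, cyst
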