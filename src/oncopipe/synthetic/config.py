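"""Shared simulation settings."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SimulationConfig:
    """Knobs shared by the simulators.

    ``read_length`` follows the study's 90 bp paired-end libraries and
    ``purity`` its assumed 70% tumor cell fraction.  ``dispersion`` is the
    negative-binomial overdispersion of count draws (0 gives Poisson).
    ``batch_bias`` maps gene_id -> multiplicative factor applied to Trizol
    samples, modelling RNA-isolation-method bias.
    """

    seed: int = 0
    read_length: int = 90
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    depth: float = 100.0  # mean pairs (coverage) or reads (pileup) per window/site
    purity: float = 0.7
    dispersion: float = 0.02
    batch_bias: dict[str, float] = field(default_factory=dict)
    n_bph_controls: int = 4
    mapq_floor: int = 30
    # rearrangement evidence planted per truth record
    n_straddling_pairs: int = 2
    n_spanning_mates: int = 8
    n_background_pairs: int = 200
    background_discordant_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.read_length < 50:
            raise ValueError("read_length must allow two 25 bp anchors")


def nb_draw(rng, mean, dispersion: float, size=None):
    """Negative-binomial draws with mean ``mean`` and variance mean*(1+dispersion*mean).

    dispersion -> 0 degenerates to Poisson.
    """
    import numpy as np

    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)
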