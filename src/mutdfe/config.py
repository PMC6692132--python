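"""Configuration objects for the synthetic-data generator and the pipeline.

All randomness flows from a single master seed through named
:class:`numpy.random.SeedSequence` substreams, so two runs with an identical
:class:`SimConfig` produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import numpy as np

__all__ = [
    "DFEMixture",
    "AssayConfig",
    "ExpressionConfig",
    "TreeConfig",
    "SimConfig",
]


@dataclass(frozen=True)
class DFEMixture:
    """Mixture describing the true distribution of selection coefficients.

    A mutation is beneficial with probability ``p_beneficial``; beneficial
    effects ``s = w - 1`` are exact generalised-Pareto draws with scale
    ``tail_tau`` and shape ``tail_kappa`` (``kappa < 0`` = bounded Weibull
    tail).  Non-beneficial effects are a two-part Gaussian mixture on
    ``s <= 0`` (truncated at ``s > -1``): a near-neutral half-normal with
    spread ``neutral_sd`` and, with weight ``p_deleterious``, a deleterious
    normal centred at ``deleterious_mean``.  Nonsense mutations draw from the
    deleterious part shifted by ``nonsense_shift``.
    """

    p_beneficial: float = 0.53
    tail_tau: float = 0.05
    tail_kappa: float = -0.35
    deleterious_mean: float = -0.05
    deleterious_sd: float = 0.03
    neutral_sd: float = 0.02
    p_deleterious: float = 0.35
    nonsense_shift: float = -0.10

    def validate(self) -> None:
        if not 0.0 <= self.p_beneficial <= 1.0:
            raise ValueError("p_beneficial must lie in [0, 1]")
        if not 0.0 <= self.p_deleterious <= 1.0:
            raise ValueError("p_deleterious must lie in [0, 1]")
        if self.tail_tau <= 0:
            raise ValueError("tail_tau must be positive")
        if not np.isfinite(self.tail_kappa):
            raise ValueError("tail_kappa must be finite")
        if self.neutral_sd < 0 or self.deleterious_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class AssayConfig:
    """Competition-assay design: replicate plates with binomial colony sampling."""

    n_replicates: int = 6
    colonies_sampled: int = 200
    doublings: float = 6.7

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.colonies_sampled < 1:
            raise ValueError("colonies_sampled must be >= 1")
        if self.doublings <= 0:
            raise ValueError("doublings must be positive")


@dataclass(frozen=True)
class ExpressionConfig:
    """Linear link between relative fitness and relative transcript level."""

    slope: float = 10.0
    intercept: float = -9.0
    noise_sd: float = 0.286

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class TreeConfig:
    """Random phylogeny with polytomies and fitness-linked tip presence.

    ``P(mutation present on >= 1 tip) = logistic(intercept + slope * log w)``;
    given presence, the number of extra carrier tips beyond the first is
    ``Binomial(n_tips - 1, carrier_extra_p)`` scattered uniformly.
    """

    n_tips: int = 77
    polytomy_fraction: float = 0.3
    presence_logit_slope: float = 15.0
    presence_logit_intercept: float = -0.6
    carrier_extra_p: float = 0.05

    def validate(self) -> None:
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if not 0.0 <= self.polytomy_fraction <= 1.0:
            raise ValueError("polytomy_fraction must lie in [0, 1]")
        if not 0.0 <= self.carrier_extra_p <= 1.0:
            raise ValueError("carrier_extra_p must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the synthetic data set.

    Defaults mirror the study conditions: 39 synonymous, 65 nonsynonymous and
    6 nonsense substitutions in a ~300-codon gene, four-to-six replicate
    competitions over ~6.7 doublings, a beneficial tail in the Weibull domain
    (kappa = -0.35), and a 77-tip phylogeny with polytomies.
    """

    seed: int = 0
    n_syn: int = 39
    n_nonsyn: int = 65
    n_nonsense: int = 6
    dfe_mixture: DFEMixture = field(default_factory=DFEMixture)
    assay: AssayConfig = field(default_factory=AssayConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    gene_length_codons: int = 303

    def validate(self) -> None:
        for n in (self.n_syn, self.n_nonsyn, self.n_nonsense):
            if n < 0:
                raise ValueError("mutation counts must be >= 0")
        if self.gene_length_codons < 51:
            raise ValueError("gene_length_codons must be >= 51")
        self.dfe_mixture.validate()
        self.assay.validate()
        self.expression.validate()
        self.tree.validate()

    # -- seeding ---------------------------------------------------------
    _STREAMS = ("gene", "mutations", "dfe", "competitions", "expression",
                "tree", "states", "reference", "trna")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, reproducible substream of the master seed."""
        if stream not in self._STREAMS:
            raise KeyError(f"unknown random stream {stream!r}")
        idx = self._STREAMS.index(stream)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,)))

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimConfig":
        d = dict(d)
        for key, sub in (("dfe_mixture", DFEMixture), ("assay", AssayConfig),
                         ("expression", ExpressionConfig), ("tree", TreeConfig)):
            if key in d and isinstance(d[key], Mapping):
                d[key] = sub(**d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg
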