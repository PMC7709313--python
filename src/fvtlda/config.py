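"""Parameter containers with the model's published operating point as defaults.

Five scalars control the scoring pipeline: ``rate`` mixes the lncRNA-side and
disease-side target smoothing, ``r1``/``r2`` are the restart probabilities of
the two random walks, and ``k1``/``k2`` attenuate the similarity-weighted
votes when smoothing the binary association matrix into graded targets.
Their defaults (0.3, 0.001, 0.001, 0.008, 0.007) are the values selected by a
grid traversal of leave-one-out AUC on the curated benchmark; the kernel
bandwidth ``gamma_prime`` and the ontology decay ``delta`` follow the
conventions of the interaction-profile-kernel and semantic-similarity
literature (1 and 0.5 respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping


@dataclass(frozen=True)
class RwrConfig:
    """Restart random walk settings.

    restart
        Restart probability ``r`` in (0, 1).  Small values let the walk
        diffuse far from its seed set before teleporting back.
    tol
        Convergence threshold on the max-abs difference between successive
        iterates.
    max_iter
        Iteration cap.  At ``r = 0.001`` the geometric contraction factor is
        0.999, so ~2.3e4 iterations are needed to push the residual below
        1e-10; the cap leaves headroom above that.
    """

    restart: float = 0.001
    tol: float = 1e-10
    max_iter: int = 50_000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart < 1.0:
            raise ValueError(f"restart must be in (0, 1), got {self.restart}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class TargetParams:
    """Disease-Clique target smoothing parameters (rate, k1, k2)."""

    rate: float = 0.3
    k1: float = 0.008
    k2: float = 0.007

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {self.rate}")
        for name in ("k1", "k2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class AnnConfig:
    """Single-hidden-layer network and its training protocol.

    The training data is split 3:1:1 into train/validation/test portions;
    optimisation stops at ``max_epochs``, when training MSE falls below
    ``mse_goal``, or when validation MSE has not improved for ``patience``
    consecutive epochs (the best-validation weights are restored).
    """

    hidden_size: int = 10
    max_epochs: int = 100
    mse_goal: float = 0.001
    patience: int = 15
    split: tuple[int, int, int] = (3, 1, 1)

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if len(self.split) != 3 or any(s < 1 for s in self.split):
            raise ValueError("split must be three positive integers")


@dataclass(frozen=True)
class FvtldaParams:
    """Full parameter set of the scoring pipeline."""

    rate: float = 0.3
    r1: float = 0.001
    r2: float = 0.001
    k1: float = 0.008
    k2: float = 0.007
    gamma_prime: float = 1.0
    delta: float = 0.5
    ann: AnnConfig = field(default_factory=AnnConfig)
    rwr_tol: float = 1e-10
    rwr_max_iter: int = 50_000

    def rwr_lncrna(self) -> RwrConfig:
        return RwrConfig(restart=self.r1, tol=self.rwr_tol, max_iter=self.rwr_max_iter)

    def rwr_disease(self) -> RwrConfig:
        return RwrConfig(restart=self.r2, tol=self.rwr_tol, max_iter=self.rwr_max_iter)

    def target_params(self) -> TargetParams:
        return TargetParams(rate=self.rate, k1=self.k1, k2=self.k2)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "FvtldaParams":
        """Build parameters from a flat mapping (e.g. a parsed YAML file).

        Unknown keys raise so that config typos surface immediately.
        ANN settings may be supplied nested under ``ann``.
        """
        known = {
            "rate", "r1", "r2", "k1", "k2", "gamma_prime", "delta",
            "ann", "rwr_tol", "rwr_max_iter",
        }
        extra = set(mapping) - known
        if extra:
            raise ValueError(f"unknown parameter(s): {sorted(extra)}")
        kwargs = dict(mapping)
        ann = kwargs.pop("ann", None)
        if ann is not None and not isinstance(ann, AnnConfig):
            if "split" in ann:
                ann = {**ann, "split": tuple(ann["split"])}
            ann = AnnConfig(**ann)
        if ann is not None:
            kwargs["ann"] = ann
        return cls(**kwargs)
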