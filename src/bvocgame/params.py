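"""Model parameters and simulation configuration.

All symbols follow the standard notation of the plant-signaling public-goods
game: a plant is either a BVOC emitter (E) or a non-emitter (N); herbivory
damage ``p`` is attenuated multiplicatively by the plant's own signaling
(intra-communication effect ``alpha1``) and by each emitting neighbor within
signaling range (inter-communication effect ``alpha2`` per emitter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping


def _check(name: str, value: float, lo: float, hi: float,
           lo_open: bool = True, hi_open: bool = True) -> None:
    lo_ok = value > lo if lo_open else value >= lo
    hi_ok = value < hi if hi_open else value <= hi
    if not (lo_ok and hi_ok):
        lo_b = "(" if lo_open else "["
        hi_b = ")" if hi_open else "]"
        raise ValueError(
            f"{name}={value!r} outside valid range {lo_b}{lo}, {hi}{hi_b}"
        )


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the BVOC emission game.

    Parameters
    ----------
    alpha1 : float
        Intra-communication effect, 0 < alpha1 <= 1. A multiplier on the
        emitter's own herbivory damage; smaller means stronger protection.
        alpha1 = 1 is the degenerate case of no own-signal benefit.
    alpha2 : float
        Inter-communication effect per emitting neighbor, 0 < alpha2 < 1.
        Compounds multiplicatively over the M emitters within signaling
        range (alpha2 ** M).
    p : float
        Herbivory damage rate absent any communication, 0 < p < 1.
    c : float
        Fractional fitness cost of BVOC emission, 0 <= c < 1.
    fhat : float
        Seed output absent herbivory and emission cost. It is a common
        positive factor of every fitness and cancels from colonization
        probabilities and from the sign of the replicator dynamics; kept
        as a parameter for fidelity to the fitness definitions.
    d : float
        Per-step mortality probability of occupied lattice sites, 0 <= d < 1.
    n : int
        Expected number of neighbors within signaling range (mean-field
        model only).
    r_bvoc : int
        Moore radius of BVOC signaling (lattice model only).
    r_d : int
        Moore radius of seed dispersal (lattice model only).
    """

    alpha1: float
    alpha2: float
    p: float = 0.4
    c: float = 0.1
    fhat: float = 1.0
    d: float = 0.05
    n: int = 8
    r_bvoc: int = 1
    r_d: int = 1

    def __post_init__(self) -> None:
        _check("alpha1", self.alpha1, 0.0, 1.0, hi_open=False)
        _check("alpha2", self.alpha2, 0.0, 1.0)
        _check("p", self.p, 0.0, 1.0)
        _check("c", self.c, 0.0, 1.0, lo_open=False)
        _check("d", self.d, 0.0, 1.0, lo_open=False)
        if self.fhat <= 0:
            raise ValueError(f"fhat={self.fhat!r} must be > 0")
        for name in ("n", "r_bvoc", "r_d"):
            v = getattr(self, name)
            if int(v) != v:
                raise ValueError(f"{name}={v!r} must be an integer")
        if self.n < 0:
            raise ValueError(f"n={self.n!r} must be >= 0")
        if self.r_bvoc < 1:
            raise ValueError(f"r_bvoc={self.r_bvoc!r} must be >= 1")
        if self.r_d < 1:
            raise ValueError(f"r_d={self.r_d!r} must be >= 1")

    def with_(self, **kwargs: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "alpha1": self.alpha1, "alpha2": self.alpha2, "p": self.p,
            "c": self.c, "fhat": self.fhat, "d": self.d, "n": self.n,
            "r_bvoc": self.r_bvoc, "r_d": self.r_d,
        }


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one lattice simulation.

    ``density_emitter`` / ``density_nonemitter`` are the independent
    per-site seeding probabilities of the initial state; the focal study
    seeds sparsely into a vacant lattice, e.g. (0.001, 0.001).
    """

    params: ModelParams
    L: int = 100
    steps: int = 30_000
    density_emitter: float = 0.001
    density_nonemitter: float = 0.001
    seed: int = 0
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.L < 3:
            raise ValueError(f"L={self.L!r} must be >= 3")
        if self.steps < 0:
            raise ValueError(f"steps={self.steps!r} must be >= 0")
        de, dn = self.density_emitter, self.density_nonemitter
        if de < 0 or dn < 0 or de + dn > 1:
            raise ValueError(
                f"initial densities ({de}, {dn}) must be nonnegative and sum to <= 1"
            )
        for r in (self.params.r_bvoc, self.params.r_d):
            if r >= self.L / 2:
                raise ValueError(
                    f"radius {r} >= L/2 = {self.L / 2}: periodic wraparound "
                    "would double-count sites"
                )

    def with_(self, **kwargs: Any) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {
            "L": self.L, "steps": self.steps,
            "density_emitter": self.density_emitter,
            "density_nonemitter": self.density_nonemitter,
            "seed": self.seed, "record_every": self.record_every,
        }
        d.update(self.params.to_dict())
        return d

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "SimConfig":
        m = dict(mapping)
        pkeys = ("alpha1", "alpha2", "p", "c", "fhat", "d", "n", "r_bvoc", "r_d")
        params = ModelParams(**{k: m.pop(k) for k in pkeys if k in m})
        return cls(params=params, **m)
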