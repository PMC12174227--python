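"""Configuration objects for community generation, invasion and experiments.

All defaults encode the study conditions: coefficient distributions follow the
community dynamic model (uniform rates, half-normal interaction strengths),
while quantities the model leaves open (guild sizes, native connectance) carry
the package defaults discussed in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

Range = tuple[float, float]

#: linkage rules for attaching the invader to native guilds
RULES = ("random", "most_to_least", "least_to_most")


def _check_range(name: str, rng: Sequence[float], integer: bool = False) -> None:
    lo, hi = rng
    if lo > hi:
        raise ValueError(f"{name}: min {lo} > max {hi}")
    if integer and lo < 1:
        raise ValueError(f"{name}: min must be >= 1, got {lo}")


@dataclass
class CommunityConfig:
    """Sampling configuration for native multilayer communities.

    Guild-size ranges are inclusive integer ranges. ``connectance`` is the
    Bernoulli link probability of both bipartite subnetworks (plant-mutualist
    and plant-herbivore), repaired so every species keeps at least one link.
    ``sigma_*`` are the uniform ranges the per-family half-normal standard
    deviations are drawn from.
    """

    sp_range: tuple[int, int] = (8, 8)
    sm_range: tuple[int, int] = (8, 8)
    sh_range: tuple[int, int] = (3, 3)
    connectance: float = 0.6
    # half-normal sigma ~ U[lo, hi], one draw per coefficient family
    sigma_plant_comp: Range = (0.05, 0.2)    # A_pp
    sigma_mut_comp: Range = (0.03, 0.05)     # A_mm
    sigma_herb_comp: Range = (0.03, 0.05)    # A_hh
    sigma_mutualism: Range = (0.05, 0.2)     # B_pm, B_mp
    sigma_herbivory: Range = (0.05, 0.2)     # C_ph, C_hp
    # uniform ranges for rates, self-limitation and initial abundances
    r_plant: Range = (0.5, 1.5)
    r_mut: Range = (-0.5, 0.5)
    r_herb: Range = (-1.0, 0.0)
    d_range: Range = (0.5, 1.5)
    x0_range: Range = (0.1, 10.0)
    per_entry_sigma: bool = False
    # stability screening
    max_candidates: int = 50_000
    max_screen: int = 200

    def validate(self) -> None:
        _check_range("sp_range", self.sp_range, integer=True)
        _check_range("sm_range", self.sm_range, integer=True)
        _check_range("sh_range", self.sh_range, integer=True)
        if not 0.0 < self.connectance <= 1.0:
            raise ValueError(f"connectance must be in (0, 1], got {self.connectance}")
        for name in ("sigma_plant_comp", "sigma_mut_comp", "sigma_herb_comp",
                     "sigma_mutualism", "sigma_herbivory", "r_plant", "r_mut",
                     "r_herb", "d_range", "x0_range"):
            _check_range(name, getattr(self, name))


@dataclass
class InvaderConfig:
    """Invader linkage and coefficient configuration.

    ``F1`` is the invader's normalized degree to native mutualists and ``F2``
    to native plants (link count = round(F * guild richness)).  ``rule`` picks
    which natives are linked; ``p_herb`` is the per-herbivore Bernoulli linking
    probability.  ``sigma_ki`` governs the competitive effect of natives on the
    invader and ``sigma_ik`` the (much stronger) effect of the invader on
    natives; ``same_sigma_variant`` instead draws both from the native plant
    competition range.
    """

    F1: float = 0.0
    F2: float = 0.0
    rule: str = "random"
    adaptive: bool = False
    G_k: float = 0.5
    p_herb: float = 0.6
    sigma_ki: Range = (0.3, 0.5)
    sigma_ik: Range = (5.0, 5.5)
    sigma_mut: Range = (0.05, 0.2)
    sigma_herb: Range = (0.05, 0.2)
    r_range: Range = (0.5, 1.5)
    d_range: Range = (0.5, 1.5)
    x0_range: Range = (0.1, 2.0)
    same_sigma_variant: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.F1 <= 1.0 or not 0.0 <= self.F2 <= 1.0:
            raise ValueError(f"F1, F2 must be in [0, 1], got {self.F1}, {self.F2}")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if self.G_k < 0:
            raise ValueError(f"adaptation rate G_k must be >= 0, got {self.G_k}")
        if not 0.0 <= self.p_herb <= 1.0:
            raise ValueError(f"p_herb must be in [0, 1], got {self.p_herb}")


@dataclass
class IntegrationSettings:
    """Solver settings: horizon, tolerances and the extinction threshold."""

    t_end: float = 2.0e3
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    extinction_threshold: float = 1e-6
    n_trajectory_points: int = 0  # 0 = final state only

    def validate(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class SimulationConfig:
    """Bundle of all configuration blocks used by the experiment layer."""

    community: CommunityConfig = field(default_factory=CommunityConfig)
    invader: InvaderConfig = field(default_factory=InvaderConfig)
    integration: IntegrationSettings = field(default_factory=IntegrationSettings)

    def validate(self) -> None:
        self.community.validate()
        self.invader.validate()
        self.integration.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        def build(klass, block):
            kwargs = dict(block or {})
            for k, v in kwargs.items():
                if isinstance(v, list):
                    kwargs[k] = tuple(v)
            return klass(**kwargs)

        return cls(
            community=build(CommunityConfig, d.get("community")),
            invader=build(InvaderConfig, d.get("invader")),
            integration=build(IntegrationSettings, d.get("integration")),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def scan_community_config(**overrides) -> CommunityConfig:
    """Community config with guild-size ranges wide enough for diversity scans.

    Native diversity (total richness) then spans roughly 14-34 species, the
    regime where stable native communities remain samplable at the default
    connectance.
    """
    kwargs = dict(sp_range=(6, 14), sm_range=(6, 14), sh_range=(2, 6))
    kwargs.update(overrides)
    return CommunityConfig(**kwargs)
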