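"""Sampling and stability screening of native multilayer communities.

A native community couples three guilds — plants, mutualists (pollinators) and
herbivores — through a bipartite plant-mutualist and a bipartite
plant-herbivore subnetwork, with dense within-guild competition.  Intrinsic
rates and initial abundances are uniform draws; every interaction coefficient
is a half-normal draw |N(0, sigma^2)| with one sigma per coefficient family
per community.  A community is accepted only if, integrated on its own, every
native species is still above the extinction threshold at the end of the
horizon ("stable coexistence").
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .config import CommunityConfig, IntegrationSettings

logger = logging.getLogger(__name__)

__all__ = [
    "GuildSizes",
    "NativeCommunity",
    "sample_guild_sizes",
    "sample_bipartite_adjacency",
    "sample_native_community",
    "screen_stable",
    "generate_stable_community",
    "degree_vector",
]


@dataclass(frozen=True)
class GuildSizes:
    """Richness of the three native guilds."""

    S_P: int
    S_M: int
    S_H: int

    def __post_init__(self):
        if min(self.S_P, self.S_M, self.S_H) < 1:
            raise ValueError(f"all guild sizes must be >= 1, got {self}")

    @property
    def total(self) -> int:
        """Native diversity: total richness over the three guilds."""
        return self.S_P + self.S_M + self.S_H


@dataclass
class NativeCommunity:
    """All rates, coefficients, masks and initial abundances of a native community.

    Interaction sign conventions live in the dynamics, not here: every
    coefficient is stored nonnegative (half-normal support) and the growth
    equations subtract competition/herbivory and add mutualism/consumption.
    Competition matrices ``A_*`` have zero diagonal because intraspecific
    regulation is the separate ``d_*`` term.
    """

    sizes: GuildSizes
    r_P: np.ndarray
    r_M: np.ndarray
    r_H: np.ndarray
    d_P: np.ndarray
    d_M: np.ndarray
    d_H: np.ndarray
    A_pp: np.ndarray
    A_mm: np.ndarray
    A_hh: np.ndarray
    mask_PM: np.ndarray
    mask_PH: np.ndarray
    B_pm: np.ndarray  # benefit of mutualist l to plant i
    B_mp: np.ndarray  # benefit of plant i to mutualist l
    C_ph: np.ndarray  # loss of plant i to herbivore h
    C_hp: np.ndarray  # gain of herbivore h from plant i
    x0_P: np.ndarray
    x0_M: np.ndarray
    x0_H: np.ndarray
    seed: int | None = None
    screened: bool = field(default=False, compare=False)

    # -- vector/matrix views used by the dynamics ---------------------------

    @property
    def r(self) -> np.ndarray:
        return np.concatenate([self.r_P, self.r_M, self.r_H])

    @property
    def d(self) -> np.ndarray:
        return np.concatenate([self.d_P, self.d_M, self.d_H])

    @property
    def x0(self) -> np.ndarray:
        return np.concatenate([self.x0_P, self.x0_M, self.x0_H])

    def interaction_matrix(self) -> np.ndarray:
        """Signed native interaction matrix W such that per-capita growth is
        ``r - d*x + W @ x`` for the stacked state ``x = (P, M, H)``."""
        sp, sm, sh = self.sizes.S_P, self.sizes.S_M, self.sizes.S_H
        S = sp + sm + sh
        W = np.zeros((S, S))
        W[:sp, :sp] = -self.A_pp
        W[:sp, sp:sp + sm] = self.B_pm
        W[:sp, sp + sm:] = -self.C_ph
        W[sp:sp + sm, :sp] = self.B_mp
        W[sp:sp + sm, sp:sp + sm] = -self.A_mm
        W[sp + sm:, :sp] = self.C_hp
        W[sp + sm:, sp + sm:] = -self.A_hh
        return W

    def check_invariants(self) -> None:
        """Raise AssertionError if any structural invariant is violated."""
        sp, sm, sh = self.sizes.S_P, self.sizes.S_M, self.sizes.S_H
        assert self.A_pp.shape == (sp, sp) and self.A_mm.shape == (sm, sm)
        assert self.A_hh.shape == (sh, sh)
        assert self.mask_PM.shape == (sp, sm) and self.mask_PH.shape == (sp, sh)
        for A in (self.A_pp, self.A_mm, self.A_hh):
            assert np.all(A >= 0) and np.all(np.diag(A) == 0)
        for M, mask in ((self.B_pm, self.mask_PM), (self.B_mp, self.mask_PM.T),
                        (self.C_ph, self.mask_PH), (self.C_hp, self.mask_PH.T)):
            assert np.all(M >= 0)
            assert np.all(M[mask == 0] == 0)
        assert np.all(self.mask_PM.sum(axis=1) >= 1)
        assert np.all(self.mask_PM.sum(axis=0) >= 1)
        assert np.all(self.mask_PH.sum(axis=1) >= 1)
        assert np.all(self.mask_PH.sum(axis=0) >= 1)

    # -- lossless JSON round-trip -------------------------------------------

    _ARRAYS = ("r_P", "r_M", "r_H", "d_P", "d_M", "d_H", "A_pp", "A_mm", "A_hh",
               "mask_PM", "mask_PH", "B_pm", "B_mp", "C_ph", "C_hp",
               "x0_P", "x0_M", "x0_H")

    def to_json(self) -> str:
        doc = {"sizes": [self.sizes.S_P, self.sizes.S_M, self.sizes.S_H],
               "seed": self.seed, "screened": self.screened}
        for name in self._ARRAYS:
            doc[name] = getattr(self, name).tolist()
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "NativeCommunity":
        doc = json.loads(text)
        sizes = GuildSizes(*doc["sizes"])
        kwargs = {}
        for name in cls._ARRAYS:
            dtype = np.int64 if name.startswith("mask") else np.float64
            kwargs[name] = np.asarray(doc[name], dtype=dtype)
        return cls(sizes=sizes, seed=doc["seed"], screened=doc["screened"], **kwargs)


def sample_guild_sizes(cfg: CommunityConfig, rng: np.random.Generator) -> GuildSizes:
    """Draw guild sizes uniformly over the configured inclusive integer ranges."""
    cfg.validate()
    draw = lambda lo_hi: int(rng.integers(lo_hi[0], lo_hi[1] + 1))
    return GuildSizes(draw(cfg.sp_range), draw(cfg.sm_range), draw(cfg.sh_range))


def sample_bipartite_adjacency(n_row: int, n_col: int, connectance: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(connectance) bipartite adjacency with min-degree-1 repair.

    Each entry is an independent Bernoulli(connectance) draw; afterwards every
    empty row and every empty column receives one uniformly chosen link so
    that each species keeps at least one partner.
    """
    if not 0.0 < connectance <= 1.0:
        raise ValueError(f"connectance must be in (0, 1], got {connectance}")
    mask = (rng.random((n_row, n_col)) < connectance).astype(np.int64)
    for i in np.flatnonzero(mask.sum(axis=1) == 0):
        mask[i, rng.integers(n_col)] = 1
    for j in np.flatnonzero(mask.sum(axis=0) == 0):
        mask[rng.integers(n_row), j] = 1
    return mask


def _half_normal(rng: np.random.Generator, sigma, shape, per_entry: bool,
                 sigma_range) -> np.ndarray:
    """|N(0, sigma^2)| draws; ``per_entry`` redraws sigma for each entry."""
    if per_entry:
        sig = rng.uniform(*sigma_range, size=shape)
    else:
        sig = sigma
    return np.abs(rng.normal(0.0, 1.0, size=shape)) * sig


def sample_native_community(sizes: GuildSizes, cfg: CommunityConfig,
                            rng: np.random.Generator,
                            seed: int | None = None) -> NativeCommunity:
    """Sample one native community from the configured distributions.

    One half-normal standard deviation is drawn per coefficient family
    (``A_pp``, ``A_mm``, ``A_hh``, mutualism, herbivory) and reused for every
    entry of that family, unless ``cfg.per_entry_sigma`` is set.
    """
    cfg.validate()
    sp, sm, sh = sizes.S_P, sizes.S_M, sizes.S_H
    pe = cfg.per_entry_sigma

    sig_pp = rng.uniform(*cfg.sigma_plant_comp)
    sig_mm = rng.uniform(*cfg.sigma_mut_comp)
    sig_hh = rng.uniform(*cfg.sigma_herb_comp)
    sig_pm = rng.uniform(*cfg.sigma_mutualism)
    sig_mp = rng.uniform(*cfg.sigma_mutualism)
    sig_ph = rng.uniform(*cfg.sigma_herbivory)
    sig_hp = rng.uniform(*cfg.sigma_herbivory)

    A_pp = _half_normal(rng, sig_pp, (sp, sp), pe, cfg.sigma_plant_comp)
    A_mm = _half_normal(rng, sig_mm, (sm, sm), pe, cfg.sigma_mut_comp)
    A_hh = _half_normal(rng, sig_hh, (sh, sh), pe, cfg.sigma_herb_comp)
    np.fill_diagonal(A_pp, 0.0)
    np.fill_diagonal(A_mm, 0.0)
    np.fill_diagonal(A_hh, 0.0)

    mask_PM = sample_bipartite_adjacency(sp, sm, cfg.connectance, rng)
    mask_PH = sample_bipartite_adjacency(sp, sh, cfg.connectance, rng)

    B_pm = _half_normal(rng, sig_pm, (sp, sm), pe, cfg.sigma_mutualism) * mask_PM
    B_mp = _half_normal(rng, sig_mp, (sm, sp), pe, cfg.sigma_mutualism) * mask_PM.T
    C_ph = _half_normal(rng, sig_ph, (sp, sh), pe, cfg.sigma_herbivory) * mask_PH
    C_hp = _half_normal(rng, sig_hp, (sh, sp), pe, cfg.sigma_herbivory) * mask_PH.T

    comm = NativeCommunity(
        sizes=sizes,
        r_P=rng.uniform(*cfg.r_plant, sp),
        r_M=rng.uniform(*cfg.r_mut, sm),
        r_H=rng.uniform(*cfg.r_herb, sh),
        d_P=rng.uniform(*cfg.d_range, sp),
        d_M=rng.uniform(*cfg.d_range, sm),
        d_H=rng.uniform(*cfg.d_range, sh),
        A_pp=A_pp, A_mm=A_mm, A_hh=A_hh,
        mask_PM=mask_PM, mask_PH=mask_PH,
        B_pm=B_pm, B_mp=B_mp, C_ph=C_ph, C_hp=C_hp,
        x0_P=rng.uniform(*cfg.x0_range, sp),
        x0_M=rng.uniform(*cfg.x0_range, sm),
        x0_H=rng.uniform(*cfg.x0_range, sh),
        seed=seed,
    )
    comm.check_invariants()
    return comm


def screen_stable(comm: NativeCommunity,
                  t_end: float = 2.0e3,
                  threshold: float = 1e-6) -> bool:
    """True iff every native species ends the native-only run above threshold.

    Integrates the native system (no invader terms) from the sampled initial
    abundances to ``t_end``.  Integration failure or a non-finite state counts
    as unstable (logged, never raised).
    """
    from .dynamics import integrate_native

    try:
        final = integrate_native(
            comm, IntegrationSettings(t_end=t_end, extinction_threshold=threshold))
    except Exception as exc:  # solver blow-up => unstable, not fatal
        logger.warning("native integration failed, community flagged unstable: %s", exc)
        return False
    if not np.all(np.isfinite(final)):
        logger.warning("non-finite native state at t_end, flagged unstable")
        return False
    return bool(np.all(final > threshold))


def _has_feasible_equilibrium(comm: NativeCommunity) -> bool:
    """Necessary condition for stable coexistence: the interior equilibrium
    (D - W) x* = r must exist with every component positive.

    This is a cheap linear solve used to pre-filter candidates before the
    integration screen; a community converging to a point with all species
    present must sit at such an equilibrium.
    """
    A = np.diag(comm.d) - comm.interaction_matrix()
    try:
        x_star = np.linalg.solve(A, comm.r)
    except np.linalg.LinAlgError:
        return False
    return bool(np.all(x_star > 0))


def generate_stable_community(sizes: GuildSizes, cfg: CommunityConfig,
                              rng: np.random.Generator,
                              settings: IntegrationSettings | None = None,
                              seed: int | None = None) -> NativeCommunity:
    """Rejection-sample until a community passes the stability screen.

    Candidates are drawn from :func:`sample_native_community`; those without a
    feasible interior equilibrium are rejected immediately (cheap linear
    solve), the rest face the full integration screen.  Raises RuntimeError
    when ``cfg.max_candidates`` draws or ``cfg.max_screen`` integrations are
    exhausted.
    """
    settings = settings or IntegrationSettings()
    n_screened = 0
    for _ in range(cfg.max_candidates):
        comm = sample_native_community(sizes, cfg, rng, seed=seed)
        if not _has_feasible_equilibrium(comm):
            continue
        n_screened += 1
        if screen_stable(comm, settings.t_end, settings.extinction_threshold):
            comm.screened = True
            return comm
        if n_screened >= cfg.max_screen:
            break
    raise RuntimeError(
        f"no stable community found for sizes {sizes} within "
        f"{cfg.max_candidates} candidates / {cfg.max_screen} screens")


def degree_vector(mask: np.ndarray, axis: str) -> np.ndarray:
    """Per-species link counts of a bipartite adjacency.

    ``axis='row'`` counts links of the row guild (e.g. plants in a
    plant-mutualist mask), ``axis='col'`` those of the column guild.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if axis == "row":
        return mask.sum(axis=1).astype(np.int64)
    if axis == "col":
        return mask.sum(axis=0).astype(np.int64)
    raise ValueError(f"axis must be 'row' or 'col', got {axis!r}")
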