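"""Attach an invasive plant to a screened native community.

The invader links to ``round(F1 * S_M)`` mutualists and ``round(F2 * S_P)``
native plants under one of three linkage rules (random, most-to-least degree,
least-to-most degree, with random tie-breaking), and to each herbivore
independently with probability ``p_herb``.  Coefficients are half-normal draws
whose standard deviations come from the configured uniform ranges; the
invader-on-native competition range (default U[5, 5.5]) makes the invader far
more competitive than natives, unless the same-sigma variant is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community_gen import NativeCommunity, degree_vector
from .config import InvaderConfig

__all__ = ["InvadedSystem", "select_links", "link_herbivores",
           "assemble_invaded_system", "round_half_up"]


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves rounded up (0.5 -> 1)."""
    return int(np.floor(x + 0.5))


@dataclass
class InvadedSystem:
    """A native community plus the invader's links, coefficients and state."""

    comm: NativeCommunity
    inv: InvaderConfig
    r_k: float
    d_k: float
    x0_k: float
    phi: np.ndarray        # binary plant-link vector, length S_P
    phi_prime: np.ndarray  # binary mutualist-link vector, length S_M
    varphi: np.ndarray     # binary herbivore-link vector, length S_H
    a_ki: np.ndarray       # effect of each linked native plant on the invader
    a_ik: np.ndarray       # effect of the invader on each linked native plant
    b_kl: np.ndarray       # invader benefit from each linked mutualist
    b_lk: np.ndarray       # mutualist benefit from the invader
    c_kh: np.ndarray       # invader loss to each linked herbivore
    c_hk: np.ndarray       # herbivore gain from the invader
    T_mut: float = field(init=False)

    def __post_init__(self):
        self.T_mut = float(self.b_kl.sum())
        self.check_invariants()

    def check_invariants(self) -> None:
        for vec, mask in ((self.a_ki, self.phi), (self.a_ik, self.phi),
                          (self.b_kl, self.phi_prime), (self.b_lk, self.phi_prime),
                          (self.c_kh, self.varphi), (self.c_hk, self.varphi)):
            assert vec.shape == mask.shape
            assert np.all(vec >= 0)
            assert np.all(vec[mask == 0] == 0)
        assert self.phi.sum() == round_half_up(self.inv.F2 * self.comm.sizes.S_P)
        assert self.phi_prime.sum() == round_half_up(self.inv.F1 * self.comm.sizes.S_M)

    @property
    def n_mut_links(self) -> int:
        return int(self.phi_prime.sum())

    @property
    def n_plant_links(self) -> int:
        return int(self.phi.sum())


def select_links(degrees: np.ndarray, F: float, rule: str,
                 rng: np.random.Generator) -> np.ndarray:
    """Choose ``round(F * len(degrees))`` species to link the invader to.

    ``random`` draws a uniform subset; ``most_to_least`` takes the highest
    native degrees first, ``least_to_most`` the lowest.  Ties between equal
    degrees are broken by an independent uniform shuffle so index order never
    biases the choice.  Returns a sorted index array.
    """
    degrees = np.asarray(degrees)
    n = len(degrees)
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"F must be in [0, 1], got {F}")
    k = round_half_up(F * n)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if rule == "random":
        idx = rng.choice(n, size=k, replace=False)
    elif rule in ("most_to_least", "least_to_most"):
        key = degrees if rule == "least_to_most" else -degrees
        order = np.lexsort((rng.random(n), key))
        idx = order[:k]
    else:
        raise ValueError(f"unknown linkage rule {rule!r}")
    return np.sort(idx.astype(np.int64))


def link_herbivores(S_H: int, p_herb: float, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(p_herb) link indicator per herbivore."""
    if not 0.0 <= p_herb <= 1.0:
        raise ValueError(f"p_herb must be in [0, 1], got {p_herb}")
    return (rng.random(S_H) < p_herb).astype(np.int64)


def _masked_half_normal(rng: np.random.Generator, sigma_range, mask: np.ndarray
                        ) -> np.ndarray:
    sigma = rng.uniform(*sigma_range)
    return np.abs(rng.normal(0.0, 1.0, size=mask.shape)) * sigma * mask


def assemble_invaded_system(comm: NativeCommunity, inv: InvaderConfig,
                            rng: np.random.Generator,
                            force: bool = False) -> InvadedSystem:
    """Build the full invaded system from a screened native community.

    Mutualist links are selected on the mutualists' native degrees and plant
    links on the plants' native degrees (both counted in the plant-mutualist
    subnetwork, before invasion).  Herbivore links ignore the rule machinery
    and are plain Bernoulli draws.  ``force`` skips the screened-community
    requirement (used for controlled test systems).
    """
    inv.validate()
    if not comm.screened and not force:
        raise ValueError("community has not passed the stability screen; "
                         "use generate_stable_community or force=True")

    deg_mut = degree_vector(comm.mask_PM, "col")
    deg_plant = degree_vector(comm.mask_PM, "row")

    sp, sm, sh = comm.sizes.S_P, comm.sizes.S_M, comm.sizes.S_H
    phi_prime = np.zeros(sm, dtype=np.int64)
    phi_prime[select_links(deg_mut, inv.F1, inv.rule, rng)] = 1
    phi = np.zeros(sp, dtype=np.int64)
    phi[select_links(deg_plant, inv.F2, inv.rule, rng)] = 1
    varphi = link_herbivores(sh, inv.p_herb, rng)

    sigma_ki = inv.sigma_ki
    sigma_ik = inv.sigma_ik
    if inv.same_sigma_variant:
        # supplementary variant: invader competition drawn like the natives'
        sigma_ki = sigma_ik = (0.05, 0.2)

    return InvadedSystem(
        comm=comm, inv=inv,
        r_k=float(rng.uniform(*inv.r_range)),
        d_k=float(rng.uniform(*inv.d_range)),
        x0_k=float(rng.uniform(*inv.x0_range)),
        phi=phi, phi_prime=phi_prime, varphi=varphi,
        a_ki=_masked_half_normal(rng, sigma_ki, phi),
        a_ik=_masked_half_normal(rng, sigma_ik, phi),
        b_kl=_masked_half_normal(rng, inv.sigma_mut, phi_prime),
        b_lk=_masked_half_normal(rng, inv.sigma_mut, phi_prime),
        c_kh=_masked_half_normal(rng, inv.sigma_herb, varphi),
        c_hk=_masked_half_normal(rng, inv.sigma_herb, varphi),
    )
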