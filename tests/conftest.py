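import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from invasim.community_gen import GuildSizes, NativeCommunity
from invasim.config import InvaderConfig


def build_community(r_P, r_M, r_H, d=1.0, x0=0.5, screened=True, **mats):
    """Hand-build a NativeCommunity with all interactions zero by default.

    ``mats`` may override any coefficient matrix or mask (A_pp, B_pm, ...).
    Masks default to all-ones so the >=1-link invariant holds for the tiny
    closed-form systems used in the tests.
    """
    r_P, r_M, r_H = map(np.atleast_1d, (np.asarray(r_P, float),
                                        np.asarray(r_M, float),
                                        np.asarray(r_H, float)))
    sp, sm, sh = len(r_P), len(r_M), len(r_H)
    sizes = GuildSizes(sp, sm, sh)
    ones = np.ones
    zeros = np.zeros
    d_arr = lambda n: np.full(n, d, float)
    x0_arr = lambda n: np.full(n, x0, float)
    defaults = dict(
        A_pp=zeros((sp, sp)), A_mm=zeros((sm, sm)), A_hh=zeros((sh, sh)),
        mask_PM=ones((sp, sm), dtype=np.int64),
        mask_PH=ones((sp, sh), dtype=np.int64),
        B_pm=zeros((sp, sm)), B_mp=zeros((sm, sp)),
        C_ph=zeros((sp, sh)), C_hp=zeros((sh, sp)),
        x0_P=x0_arr(sp), x0_M=x0_arr(sm), x0_H=x0_arr(sh),
        d_P=d_arr(sp), d_M=d_arr(sm), d_H=d_arr(sh),
    )
    defaults.update({k: np.asarray(v, dtype=float) if not k.startswith("mask")
                     else np.asarray(v, dtype=np.int64)
                     for k, v in mats.items()})
    return NativeCommunity(sizes=sizes, r_P=r_P, r_M=r_M, r_H=r_H,
                           screened=screened, **defaults)


def isolated_invader_config(**kw) -> InvaderConfig:
    """Invader with no links at all: F1=F2=0 and no herbivory."""
    base = dict(F1=0.0, F2=0.0, p_herb=0.0)
    base.update(kw)
    return InvaderConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
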