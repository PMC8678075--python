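"""Shared fixtures: tissue constants, study protocols and an independent
brute-force discrete-time oracle for the forward kinetic model."""

import numpy as np
import pytest

from mteasl import AcquisitionScheme, HemodynamicState, TissueConstants
from mteasl.encoding import build_protocol


@pytest.fixture(scope="session")
def constants():
    return TissueConstants()


@pytest.fixture(scope="session")
def protocols():
    """The two study protocols (Hadamard-8 and Hadamard-4)."""
    return [build_protocol(8, 400.0, 200.0), build_protocol(4, 1000.0, 600.0)]


@pytest.fixture(scope="session")
def schemes(protocols):
    return [acq for _, acq in protocols]


def brute_force_signal(ti, te, state, scheme, const, dt=1.0):
    """Discrete-time label bookkeeping across the three pools at ``dt`` ms.

    Independent of the closed-form implementation: arrival cohorts are
    enumerated explicitly; each cohort sits in the arterial pool until its
    intra-voxel transit elapses, then splits between the capillary and
    extravascular pools by the exponential exchange fraction, with the
    respective relaxation functions applied.
    """
    tau = scheme.effective_bolus
    opt = scheme.model_options
    shift = 0.0 if opt.exchange_clock == "voxel_arrival" else state.itt
    amp = 2.0 * state.m0 * state.f / 6.0e6 * const.label_efficiency
    u = np.arange(0.0, ti, dt) + dt / 2.0
    u = u[(u >= state.att) & (u < state.att + tau)]
    age = ti - u
    in_artery = age < state.itt
    s1 = amp * dt * np.sum(in_artery * np.exp(-ti / const.t1_blood))
    r = np.exp(-np.clip(age - shift, 0.0, None) / state.texch)
    arrived = ~in_artery
    s2 = amp * dt * np.sum(arrived * r * np.exp(-ti / const.t1_blood))
    s3 = amp * dt * np.sum(
        arrived * (1.0 - r) * np.exp(-u / const.t1_blood)
        * np.exp(-age / const.t1_tissue)
    )
    t2b, t2t = const.t2_blood, const.t2_tissue
    f1 = np.exp(-te / t2b)
    f3 = np.exp(-te / t2t)
    if opt.exchange_during_te:
        # transfer integral by fine Riemann sum (independent of closed form)
        dtau = 0.1
        tg = np.arange(0.0, te, dtau) + dtau / 2.0
        transfer = np.sum(
            (1.0 / state.texch) * np.exp(-tg / state.texch)
            * np.exp(-tg / t2b) * np.exp(-(te - tg) / t2t)
        ) * dtau
        f2 = np.exp(-te / t2b) * np.exp(-te / state.texch) + transfer
    else:
        f2 = np.exp(-te / t2b)
    return s1 * f1 + s2 * f2 + s3 * f3


@pytest.fixture(scope="session")
def oracle():
    return brute_force_signal
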