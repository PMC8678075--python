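"""Core domain containers: per-voxel haemodynamic state, acquisition schemes
and 4-D signal series with per-frame metadata."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class HemodynamicState:
    """Per-voxel unknowns of the kinetic model.

    Parameters
    ----------
    f : float
        Perfusion, ml/100 g/min.
    att : float
        Arterial transit time (labelling plane -> voxel), ms.
    itt : float
        Intra-voxel transit time (voxel arrival -> capillary exchange site),
        ms.  The two-compartment model is the ``itt = 0`` restriction.
    texch : float
        Water exchange time across the blood-brain barrier, ms.
    m0 : float
        Arterial longitudinal equilibrium magnetization, arbitrary units.
    """

    f: float
    att: float
    itt: float = 0.0
    texch: float = 300.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.f, self.att, self.itt, self.texch, self.m0)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite haemodynamic parameter")
        if self.f < 0 or self.att < 0 or self.itt < 0:
            raise ValueError("f, att and itt must be non-negative")
        if self.texch <= 0:
            raise ValueError("texch must be strictly positive")
        if self.m0 <= 0:
            raise ValueError("m0 must be strictly positive")

    def with_(self, **kwargs: float) -> "HemodynamicState":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ModelOptions:
    """Model-variant switches for the forward signal.

    exchange_during_te:
        When True, label still intravascular at excitation may exchange into
        tissue during the echo time, carrying blood T2 before and tissue T2
        after the transfer (closed-form two-exponential convolution).  Off by
        default: the compartment a spin occupies at excitation then sets its
        T2 for the whole echo, the convention under which the package's
        reference worked-example values are produced.
    bolus_extension_frac:
        Fractional artificial extension of the bolus duration used during
        fitting to emulate dispersion (0.15 ~= 15 %); 0 disables it.
    exchange_clock:
        "voxel_arrival" starts the exchange clock when label enters the voxel
        (the default convention of the extended model equations);
        "capillary_arrival" starts it only after the intra-voxel transit.
    """

    exchange_during_te: bool = False
    bolus_extension_frac: float = 0.0
    exchange_clock: str = "voxel_arrival"

    def __post_init__(self) -> None:
        if self.bolus_extension_frac < 0:
            raise ValueError("bolus_extension_frac must be >= 0")
        if self.exchange_clock not in ("voxel_arrival", "capillary_arrival"):
            raise ValueError(f"unknown exchange_clock {self.exchange_clock!r}")


@dataclass(frozen=True)
class AcquisitionScheme:
    """TI/TE sampling of one protocol.

    ``ti_list`` are inflow times (start of labelling to readout), ms;
    ``bolus_duration`` is the temporal width of the labelled bolus seen by one
    decoded TI (the Hadamard sub-bolus duration), ms.
    """

    ti_list: tuple
    te_list: tuple
    bolus_duration: float
    pld: float = 0.0
    model_options: ModelOptions = field(default_factory=ModelOptions)

    def __post_init__(self) -> None:
        ti = np.asarray(self.ti_list, dtype=float)
        te = np.asarray(self.te_list, dtype=float)
        if ti.size == 0 or te.size == 0:
            raise ValueError("ti_list and te_list must be non-empty")
        if not np.all(np.diff(ti) > 0):
            raise ValueError("ti_list must be strictly increasing")
        if not np.all(np.diff(te) > 0):
            raise ValueError("te_list must be strictly increasing")
        if np.any(te < 0):
            raise ValueError("te_list must be non-negative")
        if self.bolus_duration <= 0:
            raise ValueError("bolus_duration must be positive")
        if np.any(ti <= 0):
            raise ValueError("ti_list must be strictly positive")
        object.__setattr__(self, "ti_list", tuple(float(x) for x in ti))
        object.__setattr__(self, "te_list", tuple(float(x) for x in te))

    @property
    def ti(self) -> np.ndarray:
        return np.asarray(self.ti_list, dtype=float)

    @property
    def te(self) -> np.ndarray:
        return np.asarray(self.te_list, dtype=float)

    @property
    def effective_bolus(self) -> float:
        """Bolus duration including the fractional dispersion extension."""
        return self.bolus_duration * (1.0 + self.model_options.bolus_extension_frac)

    def with_options(self, **kwargs) -> "AcquisitionScheme":
        return replace(self, model_options=replace(self.model_options, **kwargs))


@dataclass
class SignalComponents:
    """Arterial (s_bl1), capillary (s_bl2) and extravascular (s_ex) signal,
    each indexed over TI (and possibly TE)."""

    s_bl1: np.ndarray
    s_bl2: np.ndarray
    s_ex: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.s_bl1 + self.s_bl2 + self.s_ex


def _check_series(volumes: np.ndarray, frame_meta: pd.DataFrame) -> None:
    if volumes.ndim != 4:
        raise ValueError("volumes must be a 4-D array (x, y, z, frames)")
    if len(frame_meta) != volumes.shape[3]:
        raise ValueError(
            f"frame metadata rows ({len(frame_meta)}) do not match the "
            f"4-D frame count ({volumes.shape[3]})"
        )


@dataclass
class DecodedSeries:
    """Decoded perfusion-weighted 4-D series; one frame per (TI, TE) pair.

    ``frame_meta`` columns: ``ti`` and ``te`` (ms).
    """

    volumes: np.ndarray
    frame_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_series(self.volumes, self.frame_meta)
        for col in ("ti", "te"):
            if col not in self.frame_meta:
                raise ValueError(f"frame_meta missing column {col!r}")

    @property
    def shape(self) -> tuple:
        return self.volumes.shape[:3]

    def voxel(self, idx: Sequence[int]) -> np.ndarray:
        return self.volumes[tuple(idx)]

    def concat(self, other: "DecodedSeries") -> "DecodedSeries":
        if self.shape != other.shape:
            raise ValueError("spatial shapes differ")
        return DecodedSeries(
            np.concatenate([self.volumes, other.volumes], axis=3),
            pd.concat([self.frame_meta, other.frame_meta], ignore_index=True),
        )


@dataclass
class EncodedSeries:
    """Hadamard-encoded 4-D series; one frame per (acquisition row, TE).

    ``frame_meta`` columns: ``row`` (Hadamard acquisition index) and ``te``.
    """

    volumes: np.ndarray
    frame_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_series(self.volumes, self.frame_meta)
        for col in ("row", "te"):
            if col not in self.frame_meta:
                raise ValueError(f"frame_meta missing column {col!r}")

    @property
    def shape(self) -> tuple:
        return self.volumes.shape[:3]
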