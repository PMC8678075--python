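"""Hadamard time-encoding and decoding of ASL acquisitions.

A Hadamard time-encoded pCASL labelling train is split into ``order - 1``
sub-boluses, each played as label or control according to one row of a
(Sylvester) Hadamard matrix with its constant column dropped.  Linear
decoding recovers one perfusion-weighted image per sub-bolus, i.e. one per
inflow time ``TI_k = PLD + k * SBD``, with white noise reduced by the
averaging over all acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import hadamard as _sylvester

from .types import AcquisitionScheme, DecodedSeries, EncodedSeries, ModelOptions

__all__ = ["HadamardScheme", "build_protocol", "encode", "decode"]

#: eight echo times (ms) of the two study protocols
STUDY_TE_MS = (13.84, 41.52, 69.2, 96.88, 124.56, 152.24, 179.92, 207.6)


@dataclass(frozen=True)
class HadamardScheme:
    """Hadamard time-encoding scheme of one protocol.

    ``matrix`` is the ``order x (order - 1)`` sign grid (+1 = control,
    -1 = label) obtained from a Sylvester Hadamard matrix by dropping the
    constant column.  Column ``j`` encodes the sub-bolus played ``j``-th in
    the train; the earliest-played sub-bolus has the longest TI, so column
    ``j`` decodes to ``TI = pld + (order - 1 - j) * sbd``.
    """

    order: int
    sub_bolus_duration: float
    pld: float
    matrix: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.order not in (4, 8):
            raise ValueError(f"unsupported Hadamard order {self.order}")
        if self.sub_bolus_duration <= 0 or self.pld <= 0:
            raise ValueError("sub_bolus_duration and pld must be positive")
        if self.matrix is None:
            m = _sylvester(self.order)[:, 1:]  # drop the constant column
            object.__setattr__(self, "matrix", m.astype(float))
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.order, self.order - 1):
            raise ValueError("matrix must be order x (order - 1)")
        if not np.allclose(m.T @ m, self.order * np.eye(self.order - 1)):
            raise ValueError("matrix columns must be mutually orthogonal")
        if not np.allclose(m.sum(axis=0), 0):
            raise ValueError("matrix columns must sum to zero")
        object.__setattr__(self, "matrix", m)

    @property
    def n_ti(self) -> int:
        return self.order - 1

    @property
    def ti_ms(self) -> np.ndarray:
        """Decoded inflow times, ascending, ms."""
        k = np.arange(1, self.order)
        return self.pld + k * self.sub_bolus_duration

    def column_ti(self, j: int) -> float:
        """TI decoded from matrix column ``j`` (earliest sub-bolus = longest TI)."""
        return float(self.pld + (self.order - 1 - j) * self.sub_bolus_duration)


def build_protocol(order: int, sbd: float, pld: float, te_list=STUDY_TE_MS,
                   model_options: ModelOptions | None = None):
    """Construct the Hadamard scheme and matching acquisition scheme.

    ``TI_k = pld + k * sbd`` for ``k = 1 .. order - 1``; the decoded bolus
    width per TI equals the sub-bolus duration.
    """
    had = HadamardScheme(order=order, sub_bolus_duration=float(sbd), pld=float(pld))
    acq = AcquisitionScheme(
        ti_list=tuple(had.ti_ms),
        te_list=tuple(te_list),
        bolus_duration=float(sbd),
        pld=float(pld),
        model_options=model_options or ModelOptions(),
    )
    return had, acq


def study_protocols(model_options: ModelOptions | None = None):
    """The two study protocols: Hadamard-8 (SBD 400, PLD 200 ms) and
    Hadamard-4 (SBD 1000, PLD 600 ms), both at the eight study echo times."""
    return [
        build_protocol(8, 400.0, 200.0, model_options=model_options),
        build_protocol(4, 1000.0, 600.0, model_options=model_options),
    ]


def encode(sub_bolus_pwis: np.ndarray, static: np.ndarray | float,
           scheme: HadamardScheme, te_list=None) -> EncodedSeries:
    """Hadamard-encode per-TI perfusion-weighted volumes (inverse of decode).

    ``sub_bolus_pwis`` has shape ``(x, y, z, n_ti[, n_te])`` ordered by
    ascending TI; acquisition row ``i`` is the static background minus the
    sum of the PWIs whose matrix entry is label (-1).
    """
    pwis = np.asarray(sub_bolus_pwis, dtype=float)
    squeeze_te = pwis.ndim == 4
    if squeeze_te:
        pwis = pwis[..., None]
    if pwis.shape[3] != scheme.n_ti:
        raise ValueError(
            f"expected {scheme.n_ti} per-TI volumes, got {pwis.shape[3]}"
        )
    n_te = pwis.shape[4]
    # reorder ascending-TI input to matrix-column order: column j carries the
    # sub-bolus decoding to TI index (order - 2 - j) of the ascending list
    ti_index_of_col = [int(round((scheme.column_ti(j) - scheme.pld)
                                 / scheme.sub_bolus_duration)) - 1
                      for j in range(scheme.n_ti)]
    pwis_cols = pwis[..., ti_index_of_col, :]
    label_weight = (scheme.matrix < 0).astype(float)  # 1 where labelled
    rows = np.asarray(static, dtype=float)[..., None, None] - np.einsum(
        "...jt,ij->...it", pwis_cols, label_weight
    )
    nx, ny, nz = rows.shape[:3]
    vols = rows.reshape(nx, ny, nz, scheme.order * n_te)
    te_values = (np.asarray(te_list, dtype=float) if te_list is not None
                 else np.arange(n_te, dtype=float))
    if te_values.size != n_te:
        raise ValueError("te_list length does not match the TE axis")
    meta = pd.DataFrame(
        {
            "row": np.repeat(np.arange(scheme.order), n_te),
            "te": np.tile(te_values, scheme.order),
        }
    )
    return EncodedSeries(volumes=vols, frame_meta=meta)


def decode(encoded: EncodedSeries, scheme: HadamardScheme,
           te_list=None) -> DecodedSeries:
    """Decode a Hadamard-encoded series into per-(TI, TE) perfusion-weighted
    volumes: ``PWI_j = (2 / order) * sum_i matrix[i, j] * (-row_i)``, applied
    independently per TE.  Frames come back ordered TI slowest, TE fastest,
    ascending."""
    meta = encoded.frame_meta.reset_index(drop=True)
    rows_present = sorted(meta["row"].unique())
    if rows_present != list(range(scheme.order)):
        raise ValueError(
            f"encoded series must contain rows 0..{scheme.order - 1}, "
            f"found {rows_present}"
        )
    tes = sorted(meta["te"].unique())
    n_te = len(tes)
    if len(meta) != scheme.order * n_te:
        raise ValueError(
            f"expected {scheme.order * n_te} frames "
            f"({scheme.order} rows x {n_te} TEs), got {len(meta)}"
        )
    nx, ny, nz = encoded.shape
    # gather rows x te in canonical order
    stacked = np.empty((nx, ny, nz, scheme.order, n_te))
    for i in range(scheme.order):
        for k, te in enumerate(tes):
            sel = meta.index[(meta["row"] == i) & (meta["te"] == te)]
            if len(sel) != 1:
                raise ValueError(f"missing or duplicate frame row={i} te={te}")
            stacked[..., i, k] = encoded.volumes[..., sel[0]]
    # +1 = control, -1 = label and label *subtracts* signal from the static
    # background, so the decoded perfusion-weighted signal comes out positive
    # with +matrix weights
    weights = (2.0 / scheme.order) * scheme.matrix  # (order, n_ti)
    pwi_cols = np.einsum("...ik,ij->...jk", stacked, weights)
    # map matrix columns to ascending TI order
    tis = [scheme.column_ti(j) for j in range(scheme.n_ti)]
    order_idx = np.argsort(tis)
    pwi = pwi_cols[..., order_idx, :]
    ti_sorted = np.asarray(tis)[order_idx]
    vols = pwi.reshape(nx, ny, nz, scheme.n_ti * n_te)
    te_values = list(te_list) if te_list is not None else tes
    meta_out = pd.DataFrame(
        {
            "ti": np.repeat(ti_sorted, n_te),
            "te": np.tile(np.asarray(te_values, dtype=float), scheme.n_ti),
        }
    )
    return DecodedSeries(volumes=vols, frame_meta=meta_out)
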