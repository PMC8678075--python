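"""Tissue and blood relaxation constants used throughout the kinetic model.

All times are milliseconds. The defaults are standard 3 T pCASL literature
values; every value can be overridden from a YAML/JSON ``constants:`` block.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Any, Mapping


@dataclass(frozen=True)
class TissueConstants:
    """Fixed relaxation and physiology constants.

    Parameters
    ----------
    t1_blood, t1_tissue : float
        Longitudinal relaxation times of arterial blood and brain tissue, ms.
    t2_blood, t2_tissue : float
        Transverse relaxation times, ms.  Multi-TE ASL exploits the fact that
        ``t2_blood > t2_tissue`` at 3 T, so the echo-time decay of the signal
        encodes how much label has exchanged into tissue.
    partition_coeff : float
        Blood-brain partition coefficient of water (lambda), ml/g.
    label_efficiency : float
        pCASL labelling efficiency (alpha), dimensionless in (0, 1].
    """

    t1_blood: float = 1650.0
    t1_tissue: float = 1330.0
    t2_blood: float = 150.0
    t2_tissue: float = 90.0
    partition_coeff: float = 0.9
    label_efficiency: float = 0.85

    def __post_init__(self) -> None:
        for name in ("t1_blood", "t1_tissue", "t2_blood", "t2_tissue",
                     "partition_coeff", "label_efficiency"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.label_efficiency > 1:
            raise ValueError("label_efficiency must be <= 1")
        if self.t2_blood >= self.t1_blood:
            raise ValueError("t2_blood must be smaller than t1_blood")
        if self.t2_tissue >= self.t1_tissue:
            raise ValueError("t2_tissue must be smaller than t1_tissue")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "TissueConstants":
        return cls(**{k: float(v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs: float) -> "TissueConstants":
        return replace(self, **kwargs)
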