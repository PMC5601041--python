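"""Re-referencing of scalp recordings: AR, LM, CZ and REST.

Every recording carries a ``reference`` tag that each transform validates and
updates, so accidental double re-referencing fails loudly.  REST (reference
electrode standardization technique) rebuilds approximately
infinity-referenced potentials from reference-contaminated recordings via a
minimum-norm source estimate: U = G Gref+, applied as V_ir = U V_ref.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .head_model import LeadField, leadfield_for_reference
from .transforms import CommonReference, RestReference

__all__ = [
    "ScalpRecording",
    "RestOperator",
    "apply_common_reference",
    "rest_transfer_matrix",
    "rest_operator_for",
    "apply_rest",
]


@dataclass
class ScalpRecording:
    """Multichannel voltages (channels x samples, microvolts)."""

    data: np.ndarray
    labels: tuple[str, ...]
    sfreq: float
    reference: str = "infinity"
    tmin: float = 0.0
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_channels, n_samples) matching labels")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sfreq

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def pick(self, labels) -> "ScalpRecording":
        idx = [self.index(l) for l in labels]
        return replace(self, data=self.data[idx], labels=tuple(labels))

    def copy(self) -> "ScalpRecording":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class RestOperator:
    """The REST transfer matrix U with its provenance."""

    U: np.ndarray
    source_rank: int
    built_for: str          # reference tag of the data the operator expects
    sv_cutoff: float

    def __post_init__(self) -> None:
        if self.U.ndim != 2 or self.U.shape[0] != self.U.shape[1]:
            raise ValueError("U must be square (channels x channels)")


def apply_common_reference(
    rec: ScalpRecording, reference: str, exclude: tuple[str, ...] = ("VEOG", "HEOG")
) -> ScalpRecording:
    """Subtract a common reference (AR / LM / CZ / named channel) per sample.

    AR averages the scalp channels only (``exclude`` lists non-scalp labels).
    """
    tr = CommonReference(kind=reference, labels=list(rec.labels), exclude=exclude)
    try:
        tr.fit(rec.data.T)
    except ValueError as err:
        raise KeyError(str(err)) from None
    out = rec.copy()
    out.data = tr.transform(rec.data.T).T
    out.reference = reference
    return out


def rest_transfer_matrix(
    lf_inf: LeadField, lf_ref: LeadField, sv_cutoff: float = 1e-4
) -> RestOperator:
    """Build U = G Gref+ from an infinity lead field and a re-referenced one.

    The Moore-Penrose pseudoinverse is computed by SVD, truncating singular
    values below ``sv_cutoff`` times the largest.
    """
    tr = RestReference(lf_infinity=lf_inf, lf_reference=lf_ref, sv_cutoff=sv_cutoff).fit()
    return RestOperator(
        U=tr.transfer_,
        source_rank=tr.rank_,
        built_for=lf_ref.reference_tag,
        sv_cutoff=sv_cutoff,
    )


def rest_operator_for(
    lf_inf: LeadField, reference: str, sv_cutoff: float = 1e-4
) -> RestOperator:
    """Convenience: build the REST operator for data carrying ``reference``."""
    ref = reference.split(":", 1)[1] if reference.startswith("recorded:") else reference
    op = rest_transfer_matrix(lf_inf, leadfield_for_reference(lf_inf, ref), sv_cutoff)
    return replace_built_for(op, reference)


def replace_built_for(op: RestOperator, tag: str) -> RestOperator:
    return RestOperator(U=op.U, source_rank=op.source_rank, built_for=tag,
                        sv_cutoff=op.sv_cutoff)


def apply_rest(rec: ScalpRecording, op: RestOperator) -> ScalpRecording:
    """Standardize a recording to the infinity reference: V_ir = U V_ref."""
    if rec.reference != op.built_for:
        raise ValueError(
            f"recording is {rec.reference!r}-referenced but the operator was "
            f"built for {op.built_for!r} data"
        )
    if rec.n_channels != op.U.shape[0]:
        raise ValueError("channel count does not match the REST operator")
    out = rec.copy()
    out.data = op.U @ rec.data
    out.reference = "REST"
    return out
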