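"""scikit-learn-compatible transformers for EEG channel-space operations.

All transformers operate on arrays shaped (n_samples, n_channels) — time
samples are the sklearn "samples", channels the "features" — so they compose
with sklearn pipelines.  The recording-level functions in
:mod:`restcm.referencing`, :mod:`restcm.erp_pipeline` and
:mod:`restcm.center_of_mass` are thin wrappers over these.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["CommonReference", "RestReference", "LowpassDecimate", "PositiveCM"]


class CommonReference(TransformerMixin, BaseEstimator):
    """Re-reference to a common reference: 'AR', 'LM', 'CZ' or a channel label.

    Parameters
    ----------
    kind : str
        'AR' (mean of scalp channels), 'LM' (mean of TP9/TP10), 'CZ', or any
        channel label to use as the reference electrode.
    labels : sequence of str
        Channel names matching the columns of X.
    exclude : sequence of str
        Channels left out of the AR mean (and passed through unchanged is NOT
        done here: the subtraction applies to every channel).
    """

    def __init__(self, kind="AR", labels=None, exclude=("VEOG", "HEOG")):
        self.kind = kind
        self.labels = labels
        self.exclude = exclude

    def fit(self, X, y=None):
        X = check_array(X)
        labels = list(self.labels) if self.labels is not None else [
            f"ch{i}" for i in range(X.shape[1])
        ]
        if len(labels) != X.shape[1]:
            raise ValueError("labels length must match number of channels")
        if self.kind == "AR":
            keep = [i for i, l in enumerate(labels) if l not in set(self.exclude)]
            self.ref_indices_ = np.array(keep, dtype=int)
        elif self.kind == "LM":
            missing = [l for l in ("TP9", "TP10") if l not in labels]
            if missing:
                raise ValueError(f"LM reference requires channels {missing}")
            self.ref_indices_ = np.array([labels.index("TP9"), labels.index("TP10")])
        else:
            label = "Cz" if self.kind == "CZ" else self.kind
            if label not in labels:
                raise ValueError(f"reference channel {label!r} not in labels")
            self.ref_indices_ = np.array([labels.index(label)])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "ref_indices_")
        X = check_array(X)
        ref = X[:, self.ref_indices_].mean(axis=1, keepdims=True)
        return X - ref


class RestReference(TransformerMixin, BaseEstimator):
    """Reference electrode standardization technique as a transformer.

    fit() builds the transfer matrix U = G Gref+ from an infinity-referenced
    lead field and its re-referenced counterpart (minimum-norm source step via
    a truncated-SVD Moore-Penrose pseudoinverse); transform() maps
    reference-contaminated recordings to approximately infinity-referenced
    ones.

    Fitted attributes: ``transfer_`` (U, channels x channels), ``rank_``
    (retained singular values).
    """

    def __init__(self, lf_infinity=None, lf_reference=None, sv_cutoff=1e-4):
        self.lf_infinity = lf_infinity
        self.lf_reference = lf_reference
        self.sv_cutoff = sv_cutoff

    def fit(self, X=None, y=None):
        lf, lf_ref = self.lf_infinity, self.lf_reference
        if lf is None or lf_ref is None:
            raise ValueError("both lead fields are required")
        if lf.gain.shape != lf_ref.gain.shape:
            raise ValueError("lead field dimension mismatch")
        if lf.montage.labels != lf_ref.montage.labels:
            raise ValueError("lead fields must share a montage")
        if not np.any(lf_ref.gain):
            raise ValueError("degenerate (all-zero) reference lead field")
        U_, s, Vt = np.linalg.svd(lf_ref.gain, full_matrices=False)
        keep = s > self.sv_cutoff * s[0]
        self.rank_ = int(keep.sum())
        pinv = (Vt[keep].T / s[keep]) @ U_[:, keep].T
        self.transfer_ = lf.gain @ pinv
        self.n_features_in_ = lf.gain.shape[0]
        return self

    def transform(self, X):
        check_is_fitted(self, "transfer_")
        X = check_array(X)
        if X.shape[1] != self.transfer_.shape[1]:
            raise ValueError("channel count does not match the transfer matrix")
        return X @ self.transfer_.T


class LowpassDecimate(TransformerMixin, BaseEstimator):
    """Zero-phase Butterworth low-pass followed by sample picking.

    Defaults implement the ERP preprocessing: 6 Hz low-pass (4th order,
    applied forward-backward) on 500 Hz data, decimated by 2 to 250 Hz.
    """

    def __init__(self, sfreq=500.0, cutoff=6.0, order=4, decim=2):
        self.sfreq = sfreq
        self.cutoff = cutoff
        self.order = order
        self.decim = decim

    def fit(self, X=None, y=None):
        if self.cutoff >= self.sfreq / 2:
            raise ValueError("cutoff must be below the Nyquist frequency")
        self.sos_ = signal.butter(self.order, self.cutoff, fs=self.sfreq, output="sos")
        return self

    def transform(self, X):
        check_is_fitted(self, "sos_")
        X = check_array(X)
        out = signal.sosfiltfilt(self.sos_, X, axis=0)
        return np.ascontiguousarray(out[:: self.decim])


class PositiveCM(TransformerMixin, BaseEstimator):
    """Positive center of mass of each sample's scalp topography.

    Maps (n_samples, n_channels) voltages to (n_samples, dim) CM coordinates:
    the average of the electrode coordinates weighted by the strictly positive
    channel voltages.  Samples with no positive channel are NaN.
    """

    def __init__(self, coords=None, dim=2):
        self.coords = coords
        self.dim = dim

    def fit(self, X=None, y=None):
        coords = np.asarray(self.coords, dtype=float)
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        self.coords_ = coords[:, : self.dim]
        return self

    def transform(self, X):
        check_is_fitted(self, "coords_")
        X = check_array(X, ensure_all_finite="allow-nan")
        if X.shape[1] != self.coords_.shape[0]:
            raise ValueError("channel count does not match coordinates")
        w = np.where(X > 0, X, 0.0)
        tot = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cm = (w @ self.coords_) / tot[:, None]
        cm[tot <= 0] = np.nan
        return cm
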