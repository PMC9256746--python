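"""Sample-homogeneity screening of gray-matter density maps.

Each subject's masked voxel vector is correlated with every other subject's;
a subject whose mean correlation to the rest of the sample falls strictly
below the threshold (default 0.70) is flagged as atypical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .voxels import VolumeImage, _stack


@dataclass
class QCReport:
    mean_correlation: dict  # subject_id -> mean r to all other subjects
    flagged: list
    unevaluable: list  # zero-variance subjects (flagged, with an error note)
    threshold: float
    n_input: int

    @property
    def n_excluded(self) -> int:
        return len(self.flagged)

    def to_dict(self) -> dict:
        return {"mean_correlation": self.mean_correlation,
                "flagged": list(self.flagged),
                "unevaluable": list(self.unevaluable),
                "threshold": self.threshold,
                "n_input": self.n_input, "n_excluded": self.n_excluded}


def homogeneity_check(volumes, mask: np.ndarray | None = None,
                      threshold: float = 0.70) -> QCReport:
    """Flag subjects whose mean voxelwise correlation to all others is below
    ``threshold`` (strict <).

    ``volumes`` is a list of :class:`VolumeImage` (or 3D arrays), or a
    pre-stacked (n_subjects, n_voxels) matrix.  The default mask keeps
    voxels with nonzero variance across subjects.  Subjects whose masked
    voxel vector has zero variance cannot be correlated; they are recorded
    as unevaluable and flagged rather than silently passed.
    """
    if isinstance(volumes, np.ndarray) and volumes.ndim == 2:
        X = np.asarray(volumes, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
        if mask is not None:
            X = X[:, np.asarray(mask).ravel().astype(bool)]
    else:
        X, shape, ids = _stack(volumes)
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise ValueError("mask shape does not match volumes")
            X = X[:, mask.ravel()]
    n = X.shape[0]
    if n < 3:
        raise ValueError("homogeneity check needs at least 3 subjects")
    if mask is None:
        keep = X.var(axis=0) > 0
        if not keep.any():
            raise ValueError("mask is empty (no voxel varies across subjects)")
        X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("mask is empty")

    sd = X.std(axis=1)
    evaluable = sd > 0
    mean_r: dict = {}
    unevaluable = [ids[i] for i in range(n) if not evaluable[i]]
    idx = np.flatnonzero(evaluable)
    if idx.size >= 2:
        Xc = X[idx] - X[idx].mean(axis=1, keepdims=True)
        Xc /= np.linalg.norm(Xc, axis=1, keepdims=True)
        R = Xc @ Xc.T
        np.fill_diagonal(R, np.nan)
        means = np.nanmean(R, axis=1)
        for j, i in enumerate(idx):
            mean_r[ids[i]] = float(means[j])
    flagged = [sid for sid, r in mean_r.items() if r < threshold]
    flagged += unevaluable
    return QCReport(mean_correlation=mean_r, flagged=flagged,
                    unevaluable=unevaluable, threshold=threshold, n_input=n)
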