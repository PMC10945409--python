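"""Moving-window membrane-activity scan.

Each window of a precursor is summarized by four physicochemical
descriptors — net charge, mean Kyte-Doolittle hydropathy, the Eisenberg
hydrophobic moment at the ideal alpha-helical twist of 100 deg/residue, and
the hydropathy contrast between the two helical faces.  A standardized
logistic-regression model maps the descriptors to a per-window probability
of membrane activity (the sigma score); peptides are ranked by their mean
sigma over all windows.

The model is trained on windows of user-supplied positive (membrane-active)
and negative (inactive) peptide sets and serializes to JSON, so a scan is
exactly reproducible from the model file alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .peptides import CHARGE, KYTE_DOOLITTLE, Peptide

HELIX_TWIST_DEG = 100.0

DESCRIPTOR_NAMES = (
    "net_charge",
    "mean_hydrophobicity",
    "hydrophobic_moment",
    "amphipathic_contrast",
)


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class WindowDescriptor:
    start: int  # 1-based window start
    net_charge: float
    mean_hydrophobicity: float
    hydrophobic_moment: float
    amphipathic_contrast: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.net_charge,
                self.mean_hydrophobicity,
                self.hydrophobic_moment,
                self.amphipathic_contrast,
            ]
        )


@dataclass(frozen=True)
class ScanProfile:
    peptide_id: str
    window_len: int
    starts: tuple[int, ...]
    sigmas: tuple[float, ...]

    @property
    def mean_sigma(self) -> float:
        """Arithmetic mean sigma; NaN for peptides shorter than the window."""
        if not self.sigmas:
            return float("nan")
        return float(np.mean(self.sigmas))

    @property
    def max_sigma(self) -> float:
        return float(np.max(self.sigmas)) if self.sigmas else float("nan")

    @property
    def argmax_start(self) -> int:
        if not self.sigmas:
            return 0
        return self.starts[int(np.argmax(self.sigmas))]


def window_descriptors(p: Peptide, window_len: int) -> list[WindowDescriptor]:
    """One descriptor per length-``window_len`` window at step 1.

    The hydrophobic moment is ``|sum_j h_j (cos j*delta, sin j*delta)| / n``
    with ``delta`` = 100 deg; the amphipathic contrast splits residues into
    the helical face aligned with the moment vector versus the opposite
    face and subtracts their mean hydropathies.
    """
    if window_len < 5:
        raise ScanError(f"window_len must be >= 5, got {window_len}")
    seq = p.sequence
    out: list[WindowDescriptor] = []
    delta = math.radians(HELIX_TWIST_DEG)
    for start in range(0, len(seq) - window_len + 1):
        window = seq[start : start + window_len]
        h = [KYTE_DOOLITTLE[aa] for aa in window]
        q = sum(CHARGE.get(aa, 0.0) for aa in window)
        mx = sum(hj * math.cos(j * delta) for j, hj in enumerate(h))
        my = sum(hj * math.sin(j * delta) for j, hj in enumerate(h))
        moment = math.hypot(mx, my) / window_len
        contrast = _face_contrast(h, mx, my, delta)
        out.append(
            WindowDescriptor(
                start=start + 1,
                net_charge=float(q),
                mean_hydrophobicity=float(sum(h) / window_len),
                hydrophobic_moment=float(moment),
                amphipathic_contrast=float(contrast),
            )
        )
    return out


def _face_contrast(h: Sequence[float], mx: float, my: float, delta: float) -> float:
    """Mean hydropathy of the moment-aligned face minus the opposite face."""
    if mx == 0.0 and my == 0.0:
        return 0.0
    mu = math.atan2(my, mx)
    face, anti = [], []
    for j, hj in enumerate(h):
        (face if math.cos(j * delta - mu) > 0 else anti).append(hj)
    if not face or not anti:
        return 0.0
    return sum(face) / len(face) - sum(anti) / len(anti)


@dataclass
class SigmaModel:
    """Standardized logistic model over window descriptors."""

    weights: np.ndarray
    bias: float
    mean: np.ndarray
    sd: np.ndarray
    window_len: int
    training_meta: dict = field(default_factory=dict)

    def sigma(self, descriptors: Sequence[WindowDescriptor]) -> np.ndarray:
        if not descriptors:
            return np.empty(0)
        X = np.stack([d.as_array() for d in descriptors])
        Z = (X - self.mean) / self.sd
        logit = Z @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-logit))

    # -- JSON round-trip ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "descriptors": list(DESCRIPTOR_NAMES),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "window_len": self.window_len,
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SigmaModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(obj["weights"]),
            bias=float(obj["bias"]),
            mean=np.array(obj["mean"]),
            sd=np.array(obj["sd"]),
            window_len=int(obj["window_len"]),
            training_meta=obj.get("training_meta", {}),
        )


def _window_matrix(peptides: Sequence[Peptide], window_len: int) -> np.ndarray:
    rows = []
    for p in peptides:
        for d in window_descriptors(p, window_len):
            rows.append(d.as_array())
    if not rows:
        raise ScanError("no windows: all peptides shorter than the window")
    return np.stack(rows)


def train_sigma_model(
    pos: Sequence[Peptide],
    neg: Sequence[Peptide],
    window_len: int = 19,
    seed: int = 0,
    holdout_frac: float = 0.3,
) -> SigmaModel:
    """Fit the logistic sigma model on all windows of both training sets.

    Descriptors are standardized by the training-split mean/sd, which are
    stored in the model and reapplied unchanged at scan time.  A held-out
    window fraction estimates accuracy; the fit is deterministic for a
    given (pos, neg, seed).
    """
    if not pos or not neg:
        raise ScanError("both a positive and a negative training set are required")
    Xp = _window_matrix(pos, window_len)
    Xn = _window_matrix(neg, window_len)
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xn))])
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=holdout_frac, random_state=seed, stratify=y
    )
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit((Xtr - mean) / sd, ytr)
    acc = float(clf.score((Xte - mean) / sd, yte))
    return SigmaModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        mean=mean,
        sd=sd,
        window_len=window_len,
        training_meta={
            "seed": seed,
            "n_pos_windows": int(len(Xp)),
            "n_neg_windows": int(len(Xn)),
            "holdout_accuracy": acc,
        },
    )


def scan(p: Peptide, model: SigmaModel) -> ScanProfile:
    """Per-window sigma profile of one peptide under a trained model."""
    descriptors = window_descriptors(p, model.window_len)
    sigmas = model.sigma(descriptors)
    return ScanProfile(
        peptide_id=p.id,
        window_len=model.window_len,
        starts=tuple(d.start for d in descriptors),
        sigmas=tuple(float(s) for s in sigmas),
    )


def rank_candidates(
    profiles: Sequence[ScanProfile], threshold: float = 0.5
) -> list[ScanProfile]:
    """Profiles with mean sigma >= threshold, best first; ties broken by id."""
    eligible = [pr for pr in profiles if pr.sigmas and pr.mean_sigma >= threshold]
    return sorted(eligible, key=lambda pr: (-pr.mean_sigma, pr.peptide_id))


def scan_table(profiles: Sequence[ScanProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [pr.peptide_id for pr in profiles],
            "n_windows": [len(pr.sigmas) for pr in profiles],
            "mean_sigma": [round(pr.mean_sigma, 6) for pr in profiles],
            "max_sigma": [round(pr.max_sigma, 6) for pr in profiles],
            "argmax_start": [pr.argmax_start for pr in profiles],
        }
    )


def window_table(profiles: Sequence[ScanProfile]) -> pd.DataFrame:
    rows = []
    for pr in profiles:
        for start, sigma in zip(pr.starts, pr.sigmas):
            rows.append({"id": pr.peptide_id, "start": start, "sigma": round(sigma, 6)})
    return pd.DataFrame(rows, columns=["id", "start", "sigma"])
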