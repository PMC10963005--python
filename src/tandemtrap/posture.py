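"""Posture features and leader/follower role inference.

A tandem leaves a directional signature in the pair's static posture: the
follower's head rides at the leader's abdomen tip, so the female-tip to
male-head distance differs systematically from the female-head to
male-tip distance.  For role inference each individual's head position is
summarised by its distance to the partner's head, pronotum border, and
abdomen tip, normalised by body length; an unregularised logistic
regression on the three distances classifies an individual as leader or
follower, and a PCA of the same matrix is kept for visualisation.  A
single preserved snapshot (e.g. a pair in amber) can then be scored, each
individual independently — the two role probabilities of a pair need not
be complementary.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .types import PairEvent, PostureFrame

FEATURES = ["d_head_head", "d_head_pronotum", "d_head_abdomen"]


def tip_head_distances(postures: list[PostureFrame], f_bl: float, m_bl: float) -> pd.DataFrame:
    """Per-frame fTip-mHead and fHead-mTip distances in mean body lengths.

    Frames missing any of the four points are dropped; raises if no
    complete frame remains.
    """
    mean_bl = 0.5 * (f_bl + m_bl)
    rows = []
    for fr in postures:
        if not fr.has("fTip", "mHead", "fHead", "mTip"):
            continue
        rows.append(
            (
                fr.frame_index,
                float(np.hypot(*(fr.xy("fTip") - fr.xy("mHead")))) / mean_bl,
                float(np.hypot(*(fr.xy("fHead") - fr.xy("mTip")))) / mean_bl,
            )
        )
    if not rows:
        raise ValueError("no frame has all of fTip, mHead, fHead, mTip")
    return pd.DataFrame(rows, columns=["frame_index", "d_fTip_mHead", "d_fHead_mTip"])


@dataclasses.dataclass
class RelativeHeadFeatures:
    """Focal-head-to-partner-part distances (BL units) with a role label."""

    source_id: str
    role: str  # leader | follower | unknown
    d_head_head: float
    d_head_pronotum: float
    d_head_abdomen: float

    def __post_init__(self) -> None:
        if self.role not in ("leader", "follower", "unknown"):
            raise ValueError("role must be leader|follower|unknown")
        for f in FEATURES:
            if getattr(self, f) < 0:
                raise ValueError("distances must be nonnegative")

    def vector(self) -> np.ndarray:
        return np.array([self.d_head_head, self.d_head_pronotum, self.d_head_abdomen])


def relative_head_features(
    frame: PostureFrame,
    focal_sex: str,
    norm_bl: float,
    role: str = "unknown",
    source_id: str = "",
) -> RelativeHeadFeatures | None:
    """Distances from the focal head to the partner's three body parts.

    Returns None (with a warning) when any required point is missing.
    """
    if focal_sex not in ("F", "M"):
        raise ValueError("focal_sex must be 'F' or 'M'")
    fp, pp = ("f", "m") if focal_sex == "F" else ("m", "f")
    needed = (fp + "Head", pp + "Head", pp + "Pro", pp + "Tip")
    if not frame.has(*needed):
        warnings.warn(
            f"frame {frame.frame_index}: missing point(s) for focal {focal_sex}; skipped",
            stacklevel=2,
        )
        return None
    head = frame.xy(fp + "Head")
    d = [float(np.hypot(*(head - frame.xy(pp + part)))) / norm_bl for part in ("Head", "Pro", "Tip")]
    return RelativeHeadFeatures(source_id or f"frame{frame.frame_index}", role, *d)


def features_from_events(
    events_postures: list[tuple[PairEvent, list[PostureFrame]]],
    leader_sex: str = "F",
    normalization: str = "mean_bl",
) -> pd.DataFrame:
    """Labelled per-frame feature table from posture series of known tandems.

    Each frame contributes two rows: the leader-sex individual as focal
    (labelled ``leader``) and its partner (labelled ``follower``).
    ``normalization`` picks the body length the distances are divided by:
    the pair mean (default), the partner's own, or none.
    """
    if normalization not in ("mean_bl", "partner_bl", "none"):
        raise ValueError("normalization must be mean_bl|partner_bl|none")
    rows = []
    for ev, frames in events_postures:
        bls = {"F": ev.female.body_length_mm, "M": ev.male.body_length_mm}
        for fr in frames:
            for focal in ("F", "M"):
                partner = "M" if focal == "F" else "F"
                if normalization == "mean_bl":
                    norm = 0.5 * (bls["F"] + bls["M"])
                elif normalization == "partner_bl":
                    norm = bls[partner]
                else:
                    norm = 1.0
                role = "leader" if focal == leader_sex else "follower"
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    feat = relative_head_features(
                        fr, focal, norm, role=role, source_id=f"{ev.event_id}-{fr.frame_index}-{focal}"
                    )
                if feat is not None:
                    rows.append((feat.source_id, feat.role, *feat.vector()))
    return pd.DataFrame(rows, columns=["source_id", "role", *FEATURES])


@dataclasses.dataclass
class RoleClassifier:
    """Fitted role model: feature scaling, logistic coefficients, PCA."""

    center: np.ndarray
    scale: np.ndarray
    coef: np.ndarray  # log-odds(leader) per scaled feature
    intercept: float
    n_train: int
    class_balance: float  # fraction of leader rows
    pca_loadings: np.ndarray  # (3, 3), rows are unit-norm components
    pca_explained: np.ndarray  # fractions summing to 1

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.center) / self.scale

    def predict_proba_leader(self, X: np.ndarray) -> np.ndarray:
        z = self.transform(X) @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def pca_scores(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) @ self.pca_loadings.T

    def to_json(self, path) -> None:
        obj = {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "n_train": self.n_train,
            "class_balance": self.class_balance,
            "pca_loadings": self.pca_loadings.tolist(),
            "pca_explained": self.pca_explained.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RoleClassifier":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            np.array(obj["center"]),
            np.array(obj["scale"]),
            np.array(obj["coef"]),
            float(obj["intercept"]),
            int(obj["n_train"]),
            float(obj["class_balance"]),
            np.array(obj["pca_loadings"]),
            np.array(obj["pca_explained"]),
        )


def fit_role_classifier(features: pd.DataFrame, min_per_class: int = 10) -> RoleClassifier:
    """Fit the logistic role model (and visual PCA) on labelled features.

    Features are centred and scaled to unit variance before both the
    logistic fit and the PCA (correlation-style).  The fit is
    deterministic given the data.  Perfect separation yields finite
    coefficients bounded by the optimiser's convergence tolerance, with a
    warning.
    """
    roles = features["role"]
    counts = roles.value_counts()
    if set(counts.index) != {"leader", "follower"}:
        raise ValueError("training data must contain both leader and follower rows")
    if counts.min() < min_per_class:
        raise ValueError(f"need at least {min_per_class} rows per class")
    X = features[FEATURES].to_numpy(dtype=float)
    y = (roles == "leader").to_numpy(dtype=int)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Xs = (X - center) / scale
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000, tol=1e-10)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(Xs, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        warnings.warn(
            "logistic fit did not fully converge (classes may be perfectly "
            "separated); coefficients are capped by the convergence tolerance",
            stacklevel=2,
        )
    pca = PCA(n_components=3, svd_solver="full")
    pca.fit(Xs)
    return RoleClassifier(
        center=center,
        scale=scale,
        coef=model.coef_.ravel(),
        intercept=float(model.intercept_[0]),
        n_train=int(y.size),
        class_balance=float(y.mean()),
        pca_loadings=pca.components_,
        pca_explained=pca.explained_variance_ratio_,
    )


def classify_snapshot(
    model: RoleClassifier, features: list[RelativeHeadFeatures]
) -> pd.DataFrame:
    """Score each focal individual of a snapshot independently.

    Returns one row per feature vector with ``p_leader`` and
    ``p_follower = 1 - p_leader``.  The two individuals of a pair are
    scored separately; their role probabilities carry no complementarity
    constraint.
    """
    if model is None:
        raise ValueError("unfitted model")
    rows = []
    for feat in features:
        p = float(model.predict_proba_leader(feat.vector())[0])
        rows.append((feat.source_id, p, 1.0 - p))
    return pd.DataFrame(rows, columns=["source_id", "p_leader", "p_follower"])


__all__ = [
    "FEATURES",
    "tip_head_distances",
    "RelativeHeadFeatures",
    "relative_head_features",
    "features_from_events",
    "RoleClassifier",
    "fit_role_classifier",
    "classify_snapshot",
]
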