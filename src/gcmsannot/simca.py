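"""Soft Independent Modeling of Class Analogy (SIMCA) for EI spectra.

Each chemical class (sugar, sugar phosphate, organic acid, fatty acid,
amine, ...) is modeled by its own mean-centered PCA on the m x p matrix of
normalized training spectra (p = 416 m/z bins by default).  A class model
keeps r principal directions; the residual standard deviation of the
training set,

    s0 = sqrt( sum_k sum_i e_ki^2 / ((m - r - 1)(p - r)) ),

measures how tightly the class hugs its r-dimensional subspace.  A new
object x is projected into each class subspace; its own residual SD,

    s_j = sqrt( sum_i resid_i^2 / (p - r) ),

is compared to s0 through F = s_j^2 / s0^2.  Membership is decided by the
upper tail of the F distribution: the object belongs to the class when the
residual variances are *not* significantly different (p-value > alpha).  Two
degrees-of-freedom conventions are supported:

* ``"paper"`` (default): df = (m - r - 1) and (m - r - 1)^2.
* ``"classical"``: df = (p - r) and (p - r)(m - r - 1), the textbook SIMCA
  form in which the F statistic is approximately calibrated.

An object accepted by several classes takes the class with the largest
p-value; an object accepted by none is reported as "unknown".

Class separation is summarised by the interclass distance

    D = max(0, sqrt((s12^2 + s21^2) / (s11^2 + s22^2)) - 1),

where s_qr is the residual SD of class q's training objects projected into
class r's model (df = m_q (p - r_r)) and s_qq is class q's own residual
recomputed with df = m_q (p - r_q).  D is symmetric, zero for a model
against itself, and values above one indicate genuinely distinct classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import MZ_MIN_DEFAULT

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "ClassModel",
    "ClassStats",
    "ClassificationReport",
    "DegenerateModelError",
    "fit_class_model",
    "choose_components_cv",
    "rsd_from_residual_matrix",
    "residual_sd_training",
    "project_and_residual",
    "f_test_membership",
    "classify",
    "interclass_distance",
    "important_mz",
    "cross_validate_models",
    "load_training_csv",
    "write_training_csv",
    "models_to_json",
    "models_from_json",
    "save_models",
    "load_models",
]

DF_CONVENTIONS = ("paper", "classical")


class DegenerateModelError(ValueError):
    """A class model with zero residual SD cannot support the F-test."""


@dataclass(frozen=True)
class TrainingSet:
    """Normalized training spectra of one chemical class (rows = compounds)."""

    class_name: str
    X: np.ndarray  # m x p
    compound_names: tuple[str, ...]
    mz_min: int = MZ_MIN_DEFAULT

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "compound_names", tuple(self.compound_names))
        if X.ndim != 2:
            raise ValueError(f"{self.class_name}: X must be 2-D, got {X.shape}")
        m, p = X.shape
        if m < 3:
            raise ValueError(f"{self.class_name}: need at least 3 training objects, got {m}")
        if len(self.compound_names) != m:
            raise ValueError(f"{self.class_name}: {len(self.compound_names)} names for {m} rows")
        if np.any(~X.any(axis=1)):
            raise ValueError(f"{self.class_name}: all-zero training spectrum")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def drop(self, index: int) -> "TrainingSet":
        """Training set with one object left out (for cross-validation)."""
        keep = [i for i in range(self.m) if i != index]
        return TrainingSet(
            self.class_name,
            self.X[keep],
            tuple(self.compound_names[i] for i in keep),
            self.mz_min,
        )


@dataclass(frozen=True)
class ClassModel:
    """A fitted one-class PCA model."""

    class_name: str
    mean: np.ndarray  # length p
    loadings: np.ndarray  # p x r, orthonormal columns
    r: int
    s0: float
    m: int
    p: int
    mz_min: int = MZ_MIN_DEFAULT

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        V = np.asarray(self.loadings, dtype=float)
        object.__setattr__(self, "loadings", V)
        if V.shape != (self.p, self.r):
            raise ValueError(f"loadings shape {V.shape} != ({self.p}, {self.r})")
        if self.r < 1 or self.r > min(self.m - 2, self.p):
            raise ValueError(f"r={self.r} violates 1 <= r <= min(m-2, p) for m={self.m}")
        gram = V.T @ V
        if not np.allclose(gram, np.eye(self.r), atol=1e-9):
            raise ValueError("loading columns are not orthonormal")
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")


def rsd_from_residual_matrix(E: np.ndarray, m: int, r: int) -> float:
    """Training residual SD: sqrt(sum(E^2) / ((m - r - 1)(p - r)))."""
    E = np.asarray(E, dtype=float)
    p = E.shape[1]
    dof = (m - r - 1) * (p - r)
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom: (m-r-1)(p-r) = {dof}")
    return float(np.sqrt(np.sum(E * E) / dof))


def fit_class_model(
    train: TrainingSet, r: Union[int, str] = "auto", r_max: Optional[int] = None
) -> ClassModel:
    """Mean-centered PCA model for one class via SVD.

    ``r="auto"`` picks the component count by leave-one-out cross-validation
    (:func:`choose_components_cv`), capped at ``min(5, m - 2)``.
    """
    if r == "auto":
        cap = r_max if r_max is not None else min(5, train.m - 2)
        r = choose_components_cv(train, cap)
    r = int(r)
    if train.m < r + 2:
        raise ValueError(
            f"{train.class_name}: m={train.m} too small for r={r} (need m >= r + 2)"
        )
    mean = train.X.mean(axis=0)
    Xc = train.X - mean
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:r].T  # p x r
    E = Xc - (Xc @ V) @ V.T
    s0 = rsd_from_residual_matrix(E, train.m, r)
    return ClassModel(
        class_name=train.class_name,
        mean=mean,
        loadings=V,
        r=r,
        s0=s0,
        m=train.m,
        p=train.p,
        mz_min=train.mz_min,
    )


def choose_components_cv(train: TrainingSet, r_max: int) -> int:
    """Component count by leave-one-out PRESS.

    For each held-out object the PCA is refit on the remaining m-1 rows and
    the held-out squared residual accumulated per candidate r.  Returns the
    smallest r whose PRESS is within 1% of the minimum (parsimony), never
    less than 1.
    """
    r_max = int(min(r_max, train.m - 2))
    if r_max < 1:
        raise ValueError(f"r_max must allow at least one component (m={train.m})")
    press = np.zeros(r_max)
    for i in range(train.m):
        keep = np.delete(train.X, i, axis=0)
        mean = keep.mean(axis=0)
        _, _, Vt = np.linalg.svd(keep - mean, full_matrices=False)
        d = train.X[i] - mean
        # residual sum of squares decreases as components are added
        rss = float(d @ d)
        for r in range(1, r_max + 1):
            t = Vt[r - 1] @ d
            rss -= float(t * t)
            press[r - 1] += max(rss, 0.0)
    best = float(press.min())
    for r in range(1, r_max + 1):
        if press[r - 1] <= 1.01 * best:
            return r
    return r_max  # pragma: no cover


def residual_sd_training(train: TrainingSet, model: ClassModel) -> float:
    """Recompute s0 of a fitted model on its training set."""
    Xc = train.X - model.mean
    E = Xc - (Xc @ model.loadings) @ model.loadings.T
    return rsd_from_residual_matrix(E, train.m, model.r)


def project_and_residual(
    x: np.ndarray, model: ClassModel
) -> tuple[np.ndarray, np.ndarray, float]:
    """Project an object into the class subspace.

    Returns (scores, residual vector, s_j) with
    ``s_j = sqrt(sum(resid^2) / (p - r))``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.p,):
        raise ValueError(f"object length {x.shape} != model p={model.p}")
    d = x - model.mean
    scores = model.loadings.T @ d
    residual = d - model.loadings @ scores
    s_j = float(np.sqrt(residual @ residual / (model.p - model.r)))
    return scores, residual, s_j


def f_test_membership(
    s_j: float,
    s0: float,
    m: int,
    r: int,
    alpha: float = 0.05,
    *,
    p: Optional[int] = None,
    df_convention: str = "paper",
) -> tuple[float, float, bool]:
    """F-test of the object residual variance against the class residual.

    Returns (F, p_value, member); member when p_value > alpha, i.e. the
    residual variances are not significantly different.
    """
    if df_convention not in DF_CONVENTIONS:
        raise ValueError(f"df_convention must be one of {DF_CONVENTIONS}")
    if s0 <= 0:
        raise DegenerateModelError(
            "class residual SD is zero; the membership F-test is undefined "
            "(add training objects or noise to the training set)"
        )
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    F = (s_j / s0) ** 2
    if df_convention == "paper":
        df1 = m - r - 1
        df2 = (m - r - 1) ** 2
    else:
        if p is None:
            raise ValueError("classical df convention needs the variable count p")
        df1 = p - r
        df2 = (p - r) * (m - r - 1)
    if df1 <= 0 or df2 <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df1}, {df2})")
    p_value = float(stats.f.sf(F, df1, df2))
    return float(F), p_value, p_value > alpha


@dataclass(frozen=True)
class ClassStats:
    s_j: float
    F: float
    p_value: float
    member: bool


@dataclass(frozen=True)
class ClassificationReport:
    per_class: dict[str, ClassStats]
    final_label: str  # class name or "unknown"
    multi_class: bool

    @property
    def best_p_value(self) -> float:
        return max(cs.p_value for cs in self.per_class.values())


def classify(
    x: np.ndarray,
    models: Sequence[ClassModel],
    alpha: float = 0.05,
    df_convention: str = "paper",
) -> ClassificationReport:
    """Test an object against every class model.

    The final label is the accepting class with the largest p-value, or
    "unknown" when no class accepts; ``multi_class`` is set when two or more
    classes accept.
    """
    if not models:
        raise ValueError("need at least one class model")
    p = models[0].p
    for mdl in models:
        if mdl.p != p:
            raise ValueError(
                f"model {mdl.class_name} has p={mdl.p}, expected {p}"
            )
    per_class: dict[str, ClassStats] = {}
    for mdl in models:
        _, _, s_j = project_and_residual(x, mdl)
        F, p_value, member = f_test_membership(
            s_j, mdl.s0, mdl.m, mdl.r, alpha, p=mdl.p, df_convention=df_convention
        )
        per_class[mdl.class_name] = ClassStats(s_j, F, p_value, member)
    accepting = [name for name, cs in per_class.items() if cs.member]
    if not accepting:
        label = "unknown"
    else:
        label = max(accepting, key=lambda name: per_class[name].p_value)
    return ClassificationReport(
        per_class=per_class,
        final_label=label,
        multi_class=len(accepting) >= 2,
    )


def _cross_rsd(train_q: TrainingSet, model_r: ClassModel) -> float:
    """Residual SD of class q's objects in class r's model, df = m_q (p - r_r)."""
    Xc = train_q.X - model_r.mean
    E = Xc - (Xc @ model_r.loadings) @ model_r.loadings.T
    dof = train_q.m * (model_r.p - model_r.r)
    return float(np.sqrt(np.sum(E * E) / dof))


def interclass_distance(
    model1: ClassModel,
    model2: ClassModel,
    train1: TrainingSet,
    train2: TrainingSet,
) -> float:
    """Separation between two class models (0 = indistinguishable, >1 = real).

    ``D = max(0, sqrt((s12^2 + s21^2) / (s11^2 + s22^2)) - 1)`` where s12 is
    the residual of class-1 objects in the class-2 subspace and s11/s22 are
    the own-class residuals on the same per-object df scale.
    """
    if model1.p != model2.p:
        raise ValueError("models must share the variable count p")
    s12 = _cross_rsd(train1, model2)
    s21 = _cross_rsd(train2, model1)
    s11 = _cross_rsd(train1, model1)
    s22 = _cross_rsd(train2, model2)
    denom = s11 * s11 + s22 * s22
    if denom <= 0:
        raise DegenerateModelError(
            "both classes have zero own-residual; interclass distance undefined"
        )
    return max(0.0, float(np.sqrt((s12 * s12 + s21 * s21) / denom)) - 1.0)


def important_mz(model: ClassModel, train: TrainingSet, k: int) -> list[int]:
    """The k m/z bins with the largest variance-weighted loading magnitude.

    Bin i is scored by sqrt(sum_a lambda_a * V_ia^2) over the r retained
    components, lambda_a being the component variances; ties break on lower
    m/z.  Mean-centering makes the ranking invariant to a constant added to
    every training spectrum.
    """
    if k > model.p:
        logger.warning("important_mz: k=%d > p=%d, capping", k, model.p)
        k = model.p
    Xc = train.X - model.mean
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = (S[: model.r] ** 2) / (train.m - 1)
    V = Vt[: model.r].T  # p x r
    score = np.sqrt((V * V) @ lam)
    order = np.lexsort((np.arange(model.p), -score))
    return [int(model.mz_min + i) for i in order[:k]]


def cross_validate_models(
    all_training: Sequence[TrainingSet],
    alpha: float = 0.05,
    df_convention: str = "paper",
    r: Union[int, str] = "auto",
) -> pd.DataFrame:
    """Leave-one-out class-label confusion matrix.

    Each training spectrum is held out in turn; its own class model is refit
    without it (the other class models use their full training sets) and the
    spectrum is classified against all classes.  Returns a DataFrame with
    one row per true class and one column per predicted class plus an
    ``"unknown"`` column; row sums equal the class sizes.
    """
    if len(all_training) < 2:
        raise ValueError("cross-validation needs at least 2 classes")
    names = [t.class_name for t in all_training]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names")
    # resolve r once per class on the full training set
    r_per_class: dict[str, int] = {}
    full_models: dict[str, ClassModel] = {}
    for t in all_training:
        mdl = fit_class_model(t, r=r)
        r_per_class[t.class_name] = mdl.r
        full_models[t.class_name] = mdl
    cols = names + ["unknown"]
    counts = pd.DataFrame(0, index=pd.Index(names, name="true_class"), columns=cols)
    for t in all_training:
        if t.m - 1 < 3:
            raise ValueError(
                f"{t.class_name}: class shrinks below the minimum size during LOO"
            )
        r_t = min(r_per_class[t.class_name], t.m - 3)
        for i in range(t.m):
            reduced = fit_class_model(t.drop(i), r=max(1, r_t))
            models = [
                reduced if name == t.class_name else full_models[name]
                for name in names
            ]
            report = classify(t.X[i], models, alpha, df_convention)
            counts.loc[t.class_name, report.final_label] += 1
    return counts


# ---------------------------------------------------------------------------
# Training CSV (name,class,i85..i500) and JSON model serialization
# ---------------------------------------------------------------------------

def load_training_csv(path, mz_min: int = 85, mz_max: int = 500) -> list[TrainingSet]:
    """Load per-class training sets from one CSV with a ``class`` column."""
    df = pd.read_csv(path)
    cols = [f"i{m}" for m in range(mz_min, mz_max + 1)]
    missing = [c for c in ["name", "class", *cols] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing training columns {missing[:5]}")
    sets = []
    for cls, grp in df.groupby("class", sort=False):
        sets.append(
            TrainingSet(
                class_name=str(cls),
                X=grp[cols].to_numpy(dtype=float),
                compound_names=tuple(str(n) for n in grp["name"]),
                mz_min=mz_min,
            )
        )
    return sets


def write_training_csv(sets: Sequence[TrainingSet], path) -> None:
    if not sets:
        raise ValueError("no training sets to write")
    mz_min = sets[0].mz_min
    cols = [f"i{m}" for m in range(mz_min, mz_min + sets[0].p)]
    records = []
    for t in sets:
        for name, row in zip(t.compound_names, t.X):
            rec = {"name": name, "class": t.class_name}
            rec.update(dict(zip(cols, row)))
            records.append(rec)
    pd.DataFrame.from_records(records, columns=["name", "class", *cols]).to_csv(
        path, index=False, float_format="%.10g"
    )


def models_to_json(models: Sequence[ClassModel]) -> str:
    payload = [
        {
            "class_name": mdl.class_name,
            "mean": mdl.mean.tolist(),
            "loadings": mdl.loadings.tolist(),
            "r": mdl.r,
            "s0": mdl.s0,
            "m": mdl.m,
            "p": mdl.p,
            "mz_min": mdl.mz_min,
        }
        for mdl in models
    ]
    return json.dumps({"simca_models": payload}, indent=1)


def models_from_json(text: str) -> list[ClassModel]:
    payload = json.loads(text)["simca_models"]
    return [
        ClassModel(
            class_name=d["class_name"],
            mean=np.array(d["mean"], dtype=float),
            loadings=np.array(d["loadings"], dtype=float),
            r=int(d["r"]),
            s0=float(d["s0"]),
            m=int(d["m"]),
            p=int(d["p"]),
            mz_min=int(d.get("mz_min", MZ_MIN_DEFAULT)),
        )
        for d in payload
    ]


def save_models(models: Sequence[ClassModel], path) -> None:
    with open(path, "w") as fh:
        fh.write(models_to_json(models))


def load_models(path) -> list[ClassModel]:
    with open(path) as fh:
        return models_from_json(fh.read())
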