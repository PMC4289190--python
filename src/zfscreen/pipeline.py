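"""Screening pipeline: binary defect models, tuning, two-tier gating and
dose-response readout.

The phenotype vocabulary has 11 terms. "Dead" and "Chorion" are exclusive of
everything else, and "Up Curved Tail/Fish" is the disjunction of the two
curvature terms. Per-defect one-vs-rest binary models are trained on
balanced samples; hyperparameters (classification mode, subwindow size
range, node-test family) are chosen by randomized 2/3-1/3 cross-validation.
The deployed classifier is two-tier: a three-class gate first routes each
larva to Chorion / Dead / Others, and only "Others" images are run through
the per-defect binary models (trained on Dead/Chorion-free data). Per-defect
confusion matrices over a test set account for gate carry-over: an image
wrongly gated out counts as a false negative for every defect it truly
carries, and an image wrongly gated in is scored by its binary calls.
Finally, per-concentration label counts become survival and teratogenicity
dose-response curves fitted with a four-parameter log-logistic model,
yielding LC50, EC50 and the teratogenicity index TI = LC50/EC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.svm import LinearSVC

from zfscreen.classify import (
    ModelError,
    bags_descriptor_vectors,
    predict_BAGS_descriptor,
    predict_C_vectors,
    train_bags_svm,
)
from zfscreen.ert import DIFFNEIGHBOR, SIMPLETHRES, Ensemble, ErtParams, build_ensemble
from zfscreen.subwindow import SamplerParams, image_features

# --------------------------------------------------------------------------
# vocabulary

UP_CURVED_TAIL = "Up Curved Tail"
UP_CURVED_FISH = "Up Curved Fish"
UP_CURVED_EITHER = "Up Curved Tail/Fish"

VOCABULARY = (
    "Normal",
    "Dead",
    "Chorion",
    "Down Curved Tail",
    "Hemostasis",
    "Necrosed Yolk Sac",
    "Edema",
    "Short Tail",
    UP_CURVED_TAIL,
    UP_CURVED_FISH,
    UP_CURVED_EITHER,
)

EXCLUSIVE_TERMS = ("Dead", "Chorion")
GATE_CLASSES = ("Chorion", "Dead", "Others")
#: terms handled by binary models in the second tier (everything but the gate's own)
NON_GATE_TERMS = tuple(t for t in VOCABULARY if t not in EXCLUSIVE_TERMS)


class DataError(ValueError):
    """Inconsistent labels or truth tables."""


def validate_label_set(labels: frozenset[str] | set[str]) -> frozenset[str]:
    """Check vocabulary membership, exclusivity and the curvature disjunction."""
    labels = frozenset(labels)
    unknown = labels - set(VOCABULARY)
    if unknown:
        raise DataError(f"unknown phenotype terms: {sorted(unknown)}")
    if not labels:
        raise DataError("every image needs at least one label")
    for term in EXCLUSIVE_TERMS:
        if term in labels and len(labels) > 1:
            raise DataError(f"{term!r} excludes all other terms, got {sorted(labels)}")
    either = UP_CURVED_EITHER in labels
    constituents = UP_CURVED_TAIL in labels or UP_CURVED_FISH in labels
    if either != constituents:
        raise DataError(
            f"{UP_CURVED_EITHER!r} must hold iff one of its constituents does"
        )
    return labels


def close_label_set(labels: set[str]) -> frozenset[str]:
    """Fill in the curvature disjunction term implied by its constituents."""
    labels = set(labels)
    if UP_CURVED_TAIL in labels or UP_CURVED_FISH in labels:
        labels.add(UP_CURVED_EITHER)
    return frozenset(labels)


def gate_class(labels: frozenset[str]) -> str:
    """Map a ground-truth label set to its first-tier class."""
    if "Dead" in labels:
        return "Dead"
    if "Chorion" in labels:
        return "Chorion"
    return "Others"


# --------------------------------------------------------------------------
# manifests

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV (labels ;-separated) into a validated DataFrame."""
    df = pd.read_csv(path)
    df["labels"] = [
        validate_label_set(frozenset(str(s).split(";"))) for s in df["labels"]
    ]
    return df


def write_manifest(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a manifest CSV with deterministic (sorted) label serialization."""
    out = frame.copy()
    out["labels"] = [";".join(sorted(labels)) for labels in out["labels"]]
    out.to_csv(path, index=False)


# --------------------------------------------------------------------------
# feature extraction shared by all models

def dataset_features(
    images: list[np.ndarray], sampler: SamplerParams
) -> list[np.ndarray]:
    """Per-image (n_subwindows, 768) TRGB feature clouds (float32).

    Each image uses its own RNG substream derived from (sampler.seed, image
    index), so features do not depend on processing order.
    """
    return [
        image_features(img, sampler, image_id=i).astype(np.float32)
        for i, img in enumerate(images)
    ]


# --------------------------------------------------------------------------
# image-level models (C or BAGS) over precomputed feature clouds

def default_ert_params(mode: str, test_kind: str = SIMPLETHRES, seed: int = 0) -> ErtParams:
    """T=10, K=28 and the mode's recommended N_min (1 for C, 1000 for BAGS)."""
    if mode not in ("C", "BAGS"):
        raise ValueError("mode must be 'C' or 'BAGS'")
    return ErtParams(T=10, K=28, n_min=1 if mode == "C" else 1000, test_kind=test_kind, seed=seed)


@dataclass
class TrainedModel:
    """An image classifier: ensemble (+ SVM in BAGS mode) + sampler params."""

    mode: str
    ensemble: Ensemble
    sampler: SamplerParams
    svm: LinearSVC | None = None

    @property
    def class_names(self) -> list[str]:
        if self.mode == "C":
            return list(self.ensemble.class_names)
        return [str(c) for c in self.svm.classes_]

    def predict_vectors(self, vectors: np.ndarray) -> str:
        if self.mode == "C":
            proba = predict_C_vectors(vectors, self.ensemble)
            return self.ensemble.class_names[int(np.argmax(proba))]
        if self.svm is None:
            raise ModelError("BAGS model has no SVM")
        desc = bags_descriptor_vectors(vectors, self.ensemble)
        return predict_BAGS_descriptor(desc, self.svm)

    def predict(self, img: np.ndarray, image_id: int | str = 0) -> str:
        vectors = image_features(img, self.sampler, image_id=image_id)
        return self.predict_vectors(vectors)


def train_model(
    features: list[np.ndarray],
    labels: list[str],
    mode: str,
    sampler: SamplerParams,
    ert_params: ErtParams | None = None,
) -> TrainedModel:
    """Train a C- or BAGS-mode image classifier on feature clouds.

    Subwindows inherit their image's label; in BAGS mode the forest's leaf
    vocabulary then feeds per-image descriptors to a linear SVM.
    """
    if ert_params is None:
        ert_params = default_ert_params(mode)
    class_names = sorted(set(labels))
    name_to_idx = {c: i for i, c in enumerate(class_names)}
    X = np.vstack(features)
    y = np.concatenate(
        [np.full(f.shape[0], name_to_idx[lab], dtype=np.int64) for f, lab in zip(features, labels)]
    )
    ensemble = build_ensemble(X, y, ert_params, class_names=class_names)
    svm = None
    if mode == "BAGS":
        descs = np.vstack([bags_descriptor_vectors(f, ensemble) for f in features])
        svm = train_bags_svm(descs, labels)
    return TrainedModel(mode, ensemble, sampler, svm)


# --------------------------------------------------------------------------
# binary tasks and tuning

def _stratified_subsample(
    idx: np.ndarray, frame: pd.DataFrame, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` of ``idx`` spread round-robin over distinct label sets."""
    strata: dict[tuple[str, ...], list[int]] = {}
    for i in idx:
        strata.setdefault(tuple(sorted(frame["labels"].iloc[i])), []).append(int(i))
    groups = [strata[k] for k in sorted(strata)]
    for g in groups:
        rng.shuffle(g)
    chosen: list[int] = []
    j = 0
    while len(chosen) < size and any(groups):
        g = groups[j % len(groups)]
        if g:
            chosen.append(g.pop())
        j += 1
    return np.sort(np.array(chosen, dtype=idx.dtype))


def make_binary_task(
    frame: pd.DataFrame,
    defect: str,
    balance: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Indices and YES/NO labels for one defect's one-vs-rest task.

    Positives are images whose label set contains the defect; with
    ``balance`` the majority class is randomly undersampled (seeded) to the
    minority size. The undersampling is stratified over the distinct label
    sets of the majority side (round-robin over shuffled strata), so a
    heterogeneous negative class — e.g. all defects at once when training
    the "Normal" model — stays representative instead of being dominated by
    whichever sub-class the draw happens to favor.
    """
    if defect not in VOCABULARY:
        raise ValueError(f"unknown defect {defect!r}")
    is_pos = np.array([defect in labels for labels in frame["labels"]])
    pos = np.flatnonzero(is_pos)
    neg = np.flatnonzero(~is_pos)
    if pos.size == 0 or neg.size == 0:
        raise DataError(f"task for {defect!r} needs both positives and negatives")
    if balance:
        rng = np.random.default_rng(seed & 0x7FFFFFFF)
        if pos.size > neg.size:
            pos = _stratified_subsample(pos, frame, neg.size, rng)
        elif neg.size > pos.size:
            neg = _stratified_subsample(neg, frame, pos.size, rng)
    idx = np.concatenate([pos, neg])
    pos_set = set(pos.tolist())
    y = [defect if i in pos_set else "NO" for i in idx]
    return idx, y


@dataclass(frozen=True)
class TuningGrid:
    """Hyperparameter grid searched by randomized cross-validation."""

    modes: tuple[str, ...] = ("C", "BAGS")
    size_ranges: tuple[tuple[float, float], ...] = ((0.25, 0.75), (0.5, 0.95))
    test_kinds: tuple[str, ...] = (SIMPLETHRES, DIFFNEIGHBOR)
    n_runs: int = 25
    train_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not (self.modes and self.size_ranges and self.test_kinds):
            raise ValueError("grid must be non-empty")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def points(self):
        for mode in self.modes:
            for size in self.size_ranges:
                for kind in self.test_kinds:
                    yield mode, size, kind


def _cv_accuracy(
    features: list[np.ndarray],
    labels: list[str],
    mode: str,
    sampler: SamplerParams,
    ert_params: ErtParams,
    n_runs: int,
    train_fraction: float,
    rng: np.random.Generator,
) -> float:
    n = len(features)
    accs = []
    for _ in range(n_runs):
        perm = rng.permutation(n)
        n_train = max(int(round(train_fraction * n)), 1)
        tr, te = perm[:n_train], perm[n_train:]
        if te.size == 0 or len({labels[i] for i in tr}) < 2:
            continue
        model = train_model(
            [features[i] for i in tr], [labels[i] for i in tr], mode, sampler, ert_params
        )
        hits = sum(model.predict_vectors(features[i]) == labels[i] for i in te)
        accs.append(hits / te.size)
    return float(np.mean(accs)) if accs else 0.0


def tune(
    images: list[np.ndarray],
    labels: list[str],
    grid: TuningGrid,
    n_subwindows: int = 1000,
    seed: int = 0,
) -> tuple[dict, float]:
    """Pick (mode, size range, test kind) by randomized 2/3-1/3 CV.

    Mean accuracy over ``grid.n_runs`` random splits is recorded per grid
    point; the argmax wins, ties to the first point in grid order. Returns
    the winning point as a dict plus its CV rate.
    """
    best = None
    best_rate = -1.0
    for gi, (mode, (lo, hi), kind) in enumerate(grid.points()):
        sampler = SamplerParams(n_subwindows=n_subwindows, min_frac=lo, max_frac=hi, seed=seed)
        features = dataset_features(images, sampler)
        ert_params = default_ert_params(mode, test_kind=kind, seed=seed)
        rng = np.random.default_rng((seed + 1000 * gi) & 0x7FFFFFFF)
        rate = _cv_accuracy(
            features, labels, mode, sampler, ert_params, grid.n_runs, grid.train_fraction, rng
        )
        if rate > best_rate:
            best_rate = rate
            best = {"mode": mode, "min_frac": lo, "max_frac": hi, "test_kind": kind}
    return best, best_rate


# --------------------------------------------------------------------------
# two-tier classifier

def train_three_class(
    features: list[np.ndarray],
    truths: list[frozenset[str]],
    mode: str,
    sampler: SamplerParams,
    ert_params: ErtParams | None = None,
) -> TrainedModel:
    """First-tier gate over the mutually exclusive Chorion/Dead/Others classes."""
    gate_labels = [gate_class(t) for t in truths]
    missing = set(GATE_CLASSES) - set(gate_labels)
    if missing:
        raise DataError(f"gate training set lacks classes: {sorted(missing)}")
    return train_model(features, gate_labels, mode, sampler, ert_params)


@dataclass
class TwoTierModel:
    """The deployed pipeline: gate + one binary model per non-gate term."""

    gate: TrainedModel
    binary: dict[str, TrainedModel]

    def __post_init__(self) -> None:
        missing = set(NON_GATE_TERMS) - set(self.binary)
        if missing:
            raise ModelError(f"missing binary models for: {sorted(missing)}")


def train_two_tier(
    features: list[np.ndarray],
    truths: list[frozenset[str]],
    sampler: SamplerParams,
    mode: str = "BAGS",
    test_kind: str = SIMPLETHRES,
    seed: int = 0,
) -> TwoTierModel:
    """Train gate + binary models; binaries see only Dead/Chorion-free images."""
    gate = train_three_class(
        features, truths, mode, sampler, default_ert_params(mode, test_kind, seed)
    )
    keep = [i for i, t in enumerate(truths) if gate_class(t) == "Others"]
    sub = pd.DataFrame({"labels": [truths[i] for i in keep]})
    binary: dict[str, TrainedModel] = {}
    for defect in NON_GATE_TERMS:
        idx, y = make_binary_task(sub, defect, balance=True, seed=seed)
        feats = [features[keep[i]] for i in idx]
        binary[defect] = train_model(
            feats, y, mode, sampler, default_ert_params(mode, test_kind, seed)
        )
    return TwoTierModel(gate, binary)


def two_tier_predict_vectors(
    vectors: np.ndarray, model: TwoTierModel
) -> tuple[str, frozenset[str]]:
    """(gate decision, final label set) for one image's feature cloud.

    A Dead/Chorion gate call short-circuits to a singleton label set; an
    image gated "Others" takes the union of positive binary calls (possibly
    empty — unclassified), closed under the curvature disjunction.
    """
    g = model.gate.predict_vectors(vectors)
    if g in EXCLUSIVE_TERMS:
        return g, frozenset({g})
    calls = {
        defect
        for defect, m in model.binary.items()
        if m.predict_vectors(vectors) == defect
    }
    return g, close_label_set(calls)


def two_tier_predict(
    img: np.ndarray, model: TwoTierModel, image_id: int | str = 0
) -> frozenset[str]:
    """Predict the label set of one image (empty set = unclassified)."""
    vectors = image_features(img, model.gate.sampler, image_id=image_id)
    return two_tier_predict_vectors(vectors, model)[1]


# --------------------------------------------------------------------------
# model persistence (versioned JSON; the SVM is stored by its coefficients)

def _model_to_dict(model: TrainedModel) -> dict:
    d = {
        "mode": model.mode,
        "sampler": {
            "n_subwindows": model.sampler.n_subwindows,
            "min_frac": model.sampler.min_frac,
            "max_frac": model.sampler.max_frac,
            "seed": model.sampler.seed,
        },
        "ensemble": model.ensemble.to_json(),
    }
    if model.svm is not None:
        d["svm"] = {
            "coef": model.svm.coef_.tolist(),
            "intercept": model.svm.intercept_.tolist(),
            "classes": [str(c) for c in model.svm.classes_],
        }
    return d


def _model_from_dict(d: dict) -> TrainedModel:
    sampler = SamplerParams(**d["sampler"])
    ensemble = Ensemble.from_json(d["ensemble"])
    svm = None
    if "svm" in d:
        svm = LinearSVC(C=1.0, loss="squared_hinge", dual=False)
        svm.coef_ = np.array(d["svm"]["coef"])
        svm.intercept_ = np.array(d["svm"]["intercept"])
        svm.classes_ = np.array(d["svm"]["classes"])
    return TrainedModel(d["mode"], ensemble, sampler, svm)


def save_model(model: TrainedModel, path: str | Path) -> None:
    import json

    Path(path).write_text(json.dumps(_model_to_dict(model), sort_keys=True))


def load_model(path: str | Path) -> TrainedModel:
    import json

    return _model_from_dict(json.loads(Path(path).read_text()))


def save_two_tier(model: TwoTierModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_model(model.gate, out / "gate.json")
    for defect, m in model.binary.items():
        save_model(m, out / f"binary_{defect.replace(' ', '_').replace('/', '-')}.json")


def load_two_tier(model_dir: str | Path) -> TwoTierModel:
    d = Path(model_dir)
    gate = load_model(d / "gate.json")
    binary = {
        defect: load_model(d / f"binary_{defect.replace(' ', '_').replace('/', '-')}.json")
        for defect in NON_GATE_TERMS
    }
    return TwoTierModel(gate, binary)


# --------------------------------------------------------------------------
# confusion accounting with gate carry-over

@dataclass(frozen=True)
class DefectConfusion:
    """2x2 counts for one defect over a full test set."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def aggregate_two_tier_confusion(
    gate_preds: list[str],
    binary_preds: list[dict[str, bool] | None],
    truths: list[frozenset[str]],
) -> dict[str, DefectConfusion]:
    """Per-defect confusion over the whole test set, gate carry-over included.

    ``binary_preds[i]`` maps each non-gate term to its binary call for image
    i, or is None when the gate routed the image out (Dead/Chorion), in
    which case every non-gate term is implicitly negative: a false negative
    for each true defect the image carries. Dead and Chorion themselves are
    scored from the gate decision.
    """
    if not (len(gate_preds) == len(binary_preds) == len(truths)):
        raise ValueError("gate, binary and truth lists must align")
    for t in truths:
        validate_label_set(t)
    out: dict[str, DefectConfusion] = {}
    for defect in VOCABULARY:
        tp = fp = tn = fn = 0
        for g, b, truth in zip(gate_preds, binary_preds, truths):
            truly = defect in truth
            if defect in EXCLUSIVE_TERMS:
                called = g == defect
            elif g in EXCLUSIVE_TERMS or b is None:
                called = False
            else:
                called = bool(b.get(defect, False))
            if called and truly:
                tp += 1
            elif called:
                fp += 1
            elif truly:
                fn += 1
            else:
                tn += 1
        out[defect] = DefectConfusion(tp, fp, tn, fn)
    return out


def confusion_table(confusions: dict[str, DefectConfusion]) -> pd.DataFrame:
    """Per-defect confusion counts and rates as a tidy DataFrame."""
    rows = []
    for defect, c in confusions.items():
        rows.append(
            {
                "defect": defect,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "accuracy": c.accuracy,
                "sensitivity": c.sensitivity,
                "specificity": c.specificity,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# dose-response readout

def _four_pl(logc: np.ndarray, bottom: float, top: float, log_x50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_x50 - logc)))


@dataclass
class CurveFit:
    """One fitted 4-parameter log-logistic curve (on log10 concentration)."""

    log_x50: float
    se_log_x50: float
    bottom: float
    top: float
    hill: float
    converged: bool

    @property
    def x50(self) -> float:
        return 10.0**self.log_x50


@dataclass
class DoseResponseFit:
    """Survival + teratogenicity curves and the derived LC50/EC50/TI."""

    table: pd.DataFrame
    survival: CurveFit
    teratogenicity: CurveFit

    @property
    def lc50(self) -> float:
        return self.survival.x50

    @property
    def ec50(self) -> float:
        return self.teratogenicity.x50

    @property
    def ti(self) -> float:
        return self.lc50 / self.ec50

    @property
    def log_ti(self) -> float:
        return self.survival.log_x50 - self.teratogenicity.log_x50

    @property
    def se_log_ti(self) -> float:
        # delta method on independent fits
        return float(np.hypot(self.survival.se_log_x50, self.teratogenicity.se_log_x50))


def fit_log_logistic(
    logc: np.ndarray, frac: np.ndarray, n: np.ndarray
) -> CurveFit:
    """Weighted least-squares 4PL fit of an increasing response fraction.

    Asymptotes are bounded to [0, 1] and the Hill slope kept positive; each
    point is weighted by its binomial standard error (continuity-corrected so
    fractions of 0 or 1 keep finite weight).
    """
    logc = np.asarray(logc, dtype=float)
    frac = np.asarray(frac, dtype=float)
    n = np.asarray(n, dtype=float)
    p_tilde = (frac * n + 0.5) / (n + 1.0)
    sigma = np.sqrt(p_tilde * (1 - p_tilde) / n)
    lo, hi = logc.min(), logc.max()
    order = np.argsort(logc)
    # midpoint guess: interpolated crossing of the half-range
    half = 0.5 * (frac.min() + frac.max())
    mid = float(np.interp(half, frac[order], logc[order])) if frac.max() > frac.min() else 0.5 * (lo + hi)
    mid = min(max(mid, lo), hi)
    starts = (
        [max(frac.min(), 0.0), min(max(frac.max(), 1e-3), 1.0), mid, 2.0],
        [0.02, 0.98, mid, 6.0],
        [0.02, 0.98, 0.5 * (lo + hi), 1.0],
    )
    bounds = ([0.0, 0.0, lo - 3.0, 0.05], [1.0, 1.0, hi + 3.0, 50.0])
    for p0 in starts:
        p0 = list(p0)
        p0[1] = min(max(p0[1], p0[0] + 1e-3), 1.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _four_pl,
                    logc,
                    frac,
                    p0=p0,
                    sigma=sigma,
                    absolute_sigma=True,
                    bounds=bounds,
                    maxfev=100_000,
                )
            se = float(np.sqrt(pcov[2, 2]))
            return CurveFit(
                float(popt[2]), se, float(popt[0]), float(popt[1]), float(popt[3]), True
            )
        except (RuntimeError, ValueError):
            continue
    return CurveFit(float("nan"), float("nan"), float("nan"), float("nan"), float("nan"), False)


def dose_response(classified: pd.DataFrame) -> DoseResponseFit:
    """Fit survival and teratogenicity curves from classified plate labels.

    ``classified`` needs one row per embryo with columns ``concentration``
    and ``labels`` (a set of phenotype terms). Survival fraction is
    1 - Dead fraction; the teratogenicity response among survivors is
    1 - Normal/surviving. Both responses are fitted as increasing
    log-logistic curves on log10 concentration, the control (0) mapped to a
    pseudo-log floor two decades below the lowest dose. Concentrations
    without survivors are dropped from the teratogenicity fit. If a fit
    fails to converge the raw fractions are still returned with NaN
    estimates.
    """
    if "concentration" not in classified or "labels" not in classified:
        raise ValueError("need per-embryo 'concentration' and 'labels' columns")
    rows = []
    for conc, grp in classified.groupby("concentration"):
        n = len(grp)
        n_dead = sum("Dead" in labels for labels in grp["labels"])
        n_surv = n - n_dead
        n_normal = sum(
            "Normal" in labels and "Dead" not in labels for labels in grp["labels"]
        )
        rows.append(
            {
                "concentration": float(conc),
                "n": n,
                "n_dead": n_dead,
                "n_surviving": n_surv,
                "n_normal": n_normal,
                "survival_frac": 1.0 - n_dead / n,
                "dead_frac": n_dead / n,
                "abnormal_frac": (1.0 - n_normal / n_surv) if n_surv > 0 else np.nan,
            }
        )
    table = pd.DataFrame(rows).sort_values("concentration").reset_index(drop=True)
    if len(table) < 4 or 0.0 not in table["concentration"].values:
        raise ValueError("need >= 4 concentrations including a control (0)")
    conc = table["concentration"].to_numpy()
    floor = np.log10(conc[conc > 0].min()) - 2.0
    with np.errstate(divide="ignore"):
        logc = np.where(conc > 0, np.log10(np.maximum(conc, 1e-300)), floor)
    survival_fit = fit_log_logistic(logc, table["dead_frac"].to_numpy(), table["n"].to_numpy())
    ok = table["abnormal_frac"].notna().to_numpy()
    terat_fit = fit_log_logistic(
        logc[ok], table.loc[ok, "abnormal_frac"].to_numpy(), table.loc[ok, "n_surviving"].to_numpy()
    )
    return DoseResponseFit(table, survival_fit, terat_fit)
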