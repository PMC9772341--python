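"""Binary thermophilicity classification from sequence features.

Organisms are banded into four thermal classes by optimal growth
temperature (OGT): psychrophilic (<15 C), mesophilic (25-37 C),
thermophilic (45-70 C), hyperthermophilic (>80 C); temperatures between
bands are left unlabeled.  Four binary schemes pair these classes:
PM, MT, TH and MTH (mesophilic vs thermophilic+hyperthermophilic, the
scheme deployed for triage).  Five classifier families are supported
(random forest, logistic regression, Gaussian naive Bayes, k-nearest
neighbor, support vector machine), each with a small documented
hyperparameter grid searched against a separate tuning split.

Redundancy control reimplements CD-HIT's greedy representative clustering
with exact pairwise identity (matches over the shorter sequence length),
practical at desk scale; data splits assign whole clusters to one
partition so no near-duplicate pair straddles a split.

Fitted models are held as plain parameter arrays (trees, support vectors,
coefficients, neighbor tables) and predict natively from them, so a model
serialized to JSON reproduces its in-memory predictions exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ConfigError, EvaluationError
from .features import (
    GgapDescriptor,
    enumerate_ggap_candidates,
    featurize_matrix,
    feature_names,
    ggap_matrix,
)

THERMAL_CLASSES = ("psychrophilic", "mesophilic", "thermophilic", "hyperthermophilic")

#: scheme -> (negative class, positive classes, reported positive label)
SCHEMES = {
    "PM": ("psychrophilic", ("mesophilic",), "mesophilic"),
    "MT": ("mesophilic", ("thermophilic",), "thermophilic"),
    "TH": ("thermophilic", ("hyperthermophilic",), "hyperthermophilic"),
    "MTH": ("mesophilic", ("thermophilic", "hyperthermophilic"), "thermophilic"),
}

METHODS = (
    "random_forest",
    "logistic_regression",
    "gaussian_naive_bayes",
    "k_nearest_neighbor",
    "support_vector_machine",
)

#: Small documented grids, searched in declared order (first wins ties).
DEFAULT_GRIDS = {
    "support_vector_machine": [
        {"C": c, "gamma": g} for c in (0.1, 1.0, 10.0) for g in ("scale", 0.01, 0.001)
    ],
    "logistic_regression": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "random_forest": [
        {"n_estimators": 100, "max_features": mf} for mf in ("sqrt", 0.3)
    ],
    "gaussian_naive_bayes": [{"var_smoothing": v} for v in (1e-9, 1e-8)],
    "k_nearest_neighbor": [{"n_neighbors": k} for k in (3, 5, 11)],
}

#: distance/margin methods are standardized; tree/probabilistic ones are not
STANDARDIZE = {
    "support_vector_machine": True,
    "logistic_regression": True,
    "k_nearest_neighbor": True,
    "random_forest": False,
    "gaussian_naive_bayes": False,
}


def band_ogt_to_class(ogt: float):
    """Map an OGT in deg C to a thermal class, or None between bands."""
    if not np.isfinite(ogt):
        raise ConfigError("OGT must be finite")
    if ogt < 15:
        return "psychrophilic"
    if 25 <= ogt <= 37:
        return "mesophilic"
    if 45 <= ogt <= 70:
        return "thermophilic"
    if ogt > 80:
        return "hyperthermophilic"
    return None


# --- redundancy clustering --------------------------------------------------

def _identity_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: max matched positions / shorter length."""
    a = a.residues if hasattr(a, "residues") else str(a)
    b = b.residues if hasattr(b, "residues") else str(b)
    score = _identity_aligner().score(a, b)
    return score / min(len(a), len(b))


def cluster_identity(records, threshold: float = 0.4, seed: int = 0) -> dict:
    """Greedy representative clustering at a sequence-identity threshold.

    Records are visited by decreasing length (ties by id); each joins the
    first existing cluster whose representative shares identity >=
    threshold, else founds a new cluster.  Returns id -> cluster index.
    The ordering rule makes the result deterministic; ``seed`` is accepted
    for interface symmetry and unused.
    """
    if not (0 < threshold <= 1):
        raise ConfigError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    reps: list = []
    assignment: dict[str, int] = {}
    for rec in ordered:
        for ci, rep in enumerate(reps):
            if pairwise_identity(rec, rep) >= threshold:
                assignment[rec.id] = ci
                break
        else:
            assignment[rec.id] = len(reps)
            reps.append(rec)
    return assignment


def split_by_cluster(assignment: dict, fractions=(0.8, 0.1, 0.1), seed: int = 0,
                     labels: dict | None = None, balance_tol: float = 0.1) -> dict:
    """Assign whole clusters to train/tune/validation partitions.

    Clusters are shuffled deterministically and greedily placed in the
    partition with the largest remaining deficit.  With ``labels`` given,
    every class must end up present in every partition (balance error
    otherwise) and per-class fractions are checked against ``balance_tol``.
    Returns id -> partition name.
    """
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("fractions must be three values summing to 1")
    parts = ("train", "tune", "validation")
    clusters: dict[int, list] = {}
    for rid, ci in assignment.items():
        clusters.setdefault(ci, []).append(rid)
    order = sorted(clusters)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    if len(order) == 1:
        warnings.warn("single cluster: all records assigned to one partition")
    sizes = dict.fromkeys(parts, 0)
    total = len(assignment)
    out = {}
    for ci in order:
        deficits = {
            p: fractions[i] * total - sizes[p] for i, p in enumerate(parts)
        }
        target = max(parts, key=lambda p: deficits[p])
        for rid in clusters[ci]:
            out[rid] = target
        sizes[target] += len(clusters[ci])
    if labels is not None:
        classes = sorted(set(labels.values()))
        for p in parts:
            present = {labels[r] for r, q in out.items() if q == p}
            if sizes[p] > 0 and set(classes) - present:
                raise EvaluationError(
                    f"class balance error: partition {p!r} lacks "
                    f"{sorted(set(classes) - present)}"
                )
    return out


# --- datasets ---------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Records with thermal-class labels and an aligned feature matrix."""

    records: list
    labels: list                      # thermal class per record
    features: np.ndarray | None = None
    feature_names: list | None = None
    clusters: np.ndarray | None = None

    def __post_init__(self):
        if len(self.records) != len(self.labels):
            raise ConfigError("one label per record required")
        bad = set(self.labels) - set(THERMAL_CLASSES)
        if bad:
            raise ConfigError(f"labels outside the thermal-class vocabulary: {bad}")

    def featurized(self, selected_ggap=None) -> "LabeledDataset":
        X, names = featurize_matrix(self.records, selected_ggap)
        return LabeledDataset(self.records, self.labels, X, names, self.clusters)


def dataset_from_ogt(records, selected_ggap=None, clusters: dict | None = None
                     ) -> LabeledDataset:
    """Band record OGTs into classes; drops records between bands or without OGT."""
    kept, labels = [], []
    for r in records:
        if r.ogt is None:
            continue
        cls = band_ogt_to_class(r.ogt)
        if cls is None:
            continue
        kept.append(r)
        labels.append(cls)
    cl = None
    if clusters is not None:
        cl = np.array([clusters[r.id] for r in kept])
    ds = LabeledDataset(kept, labels, clusters=cl)
    return ds.featurized(selected_ggap)


def binarize(dataset: LabeledDataset, scheme: str):
    """Select the scheme's two classes; returns (X, y, records, clusters)."""
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown scheme {scheme!r}")
    neg, pos, _ = SCHEMES[scheme]
    mask = np.array([l == neg or l in pos for l in dataset.labels])
    if dataset.features is None:
        raise ConfigError("dataset must be featurized first")
    y = np.array([1 if l in pos else 0
                  for l, m in zip(dataset.labels, mask) if m])
    X = dataset.features[mask]
    recs = [r for r, m in zip(dataset.records, mask) if m]
    cl = dataset.clusters[mask] if dataset.clusters is not None else None
    if len(set(y.tolist())) < 2:
        raise EvaluationError(f"scheme {scheme}: only one class present")
    return X, y, recs, cl


# --- g-gap feature selection ------------------------------------------------

def select_ggap_features(records, y, candidates=None, k: int = 10,
                         seed: int = 0) -> list[GgapDescriptor]:
    """Rank candidate g-gap dipeptides by random-forest Gini importance.

    ``y`` is a binary label per record.  Returns the top ``k`` descriptors,
    ranked by mean impurity decrease with ties broken lexicographically.
    """
    candidates = list(candidates) if candidates is not None else enumerate_ggap_candidates()
    if k > len(candidates):
        raise ConfigError("k exceeds the number of candidates")
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise EvaluationError("feature selection needs both classes")
    X = ggap_matrix(records, candidates)
    forest = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    imp = forest.feature_importances_
    order = sorted(range(len(candidates)), key=lambda j: (-imp[j], candidates[j]))
    return [candidates[j] for j in order[:k]]


# --- classifier spec / fitted model -----------------------------------------

@dataclass
class ClassifierSpec:
    scheme: str = "MTH"
    method: str = "support_vector_machine"
    grid: list = None
    standardize: bool | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.method not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}")
        if self.grid is None:
            self.grid = [dict(g) for g in DEFAULT_GRIDS[self.method]]
        if not self.grid:
            raise ConfigError("hyperparameter grid must be nonempty")
        if self.standardize is None:
            self.standardize = STANDARDIZE[self.method]


def _make_estimator(method: str, params: dict, seed: int):
    if method == "support_vector_machine":
        return SVC(kernel="rbf", random_state=seed, **params)
    if method == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if method == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if method == "gaussian_naive_bayes":
        return GaussianNB(**params)
    if method == "k_nearest_neighbor":
        return KNeighborsClassifier(**params)
    raise ConfigError(f"unknown method {method!r}")


def _extract_params(method: str, est, X, y) -> dict:
    if method == "logistic_regression":
        return {"coef": est.coef_[0].tolist(), "intercept": float(est.intercept_[0])}
    if method == "gaussian_naive_bayes":
        return {
            "theta": est.theta_.tolist(),
            "var": est.var_.tolist(),
            "log_prior": np.log(est.class_prior_).tolist(),
            "classes": est.classes_.tolist(),
        }
    if method == "support_vector_machine":
        return {
            "support_vectors": est.support_vectors_.tolist(),
            "dual_coef": est.dual_coef_[0].tolist(),
            "intercept": float(est.intercept_[0]),
            "gamma": float(est._gamma),
        }
    if method == "k_nearest_neighbor":
        return {
            "X": np.asarray(X).tolist(),
            "y": np.asarray(y).tolist(),
            "n_neighbors": est.n_neighbors,
        }
    if method == "random_forest":
        trees = []
        for t in est.estimators_:
            tt = t.tree_
            value = tt.value[:, 0, :]
            value = value / value.sum(axis=1, keepdims=True)
            trees.append({
                "children_left": tt.children_left.tolist(),
                "children_right": tt.children_right.tolist(),
                "feature": tt.feature.tolist(),
                "threshold": tt.threshold.tolist(),
                "value": value.tolist(),
                "classes": est.classes_.tolist(),
            })
        return {"trees": trees}
    raise ConfigError(method)


def _native_scores(method: str, params: dict, X: np.ndarray) -> np.ndarray:
    """Real-valued positive-class score from stored parameters."""
    X = np.asarray(X, dtype=float)
    if method == "logistic_regression":
        return X @ np.array(params["coef"]) + params["intercept"]
    if method == "support_vector_machine":
        sv = np.array(params["support_vectors"])
        d2 = ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        k = np.exp(-params["gamma"] * d2)
        return k @ np.array(params["dual_coef"]) + params["intercept"]
    if method == "gaussian_naive_bayes":
        theta = np.array(params["theta"])
        var = np.array(params["var"])
        jll = []
        for c in range(2):
            ll = -0.5 * np.sum(np.log(2.0 * np.pi * var[c]))
            ll = ll - 0.5 * ((X - theta[c]) ** 2 / var[c]).sum(axis=1)
            jll.append(ll + params["log_prior"][c])
        return jll[1] - jll[0]
    if method == "k_nearest_neighbor":
        Xt = np.array(params["X"])
        yt = np.array(params["y"])
        d2 = ((X[:, None, :] - Xt[None, :, :]) ** 2).sum(axis=2)
        k = params["n_neighbors"]
        idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
        frac_pos = yt[idx].mean(axis=1)
        return frac_pos - 0.5
    if method == "random_forest":
        proba = np.zeros(len(X))
        for tree in params["trees"]:
            cl = np.array(tree["children_left"])
            cr = np.array(tree["children_right"])
            feat = np.array(tree["feature"])
            thr = np.array(tree["threshold"])
            val = np.array(tree["value"])
            classes = tree["classes"]
            pos_col = classes.index(1) if 1 in classes else None
            for i, x in enumerate(X):
                node = 0
                while cl[node] != -1:
                    node = cl[node] if x[feat[node]] <= thr[node] else cr[node]
                proba[i] += val[node][pos_col] if pos_col is not None else 0.0
        return proba / len(params["trees"]) - 0.5
    raise ConfigError(method)


@dataclass
class TrainedModel:
    """A fitted binary thermophilicity classifier with its preprocessing."""

    spec: ClassifierSpec
    selected_ggap: list
    feature_names: list
    kept_idx: list              # indices of non-degenerate features
    mean: list
    sd: list
    best_params: dict
    params: dict                # native fitted parameters
    n_per_class: dict = field(default_factory=dict)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept_idx]
        if self.spec.standardize:
            X = (X - np.array(self.mean)) / np.array(self.sd)
        return X

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return _native_scores(self.spec.method, self.params, self._prepare(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) > 0).astype(int)

    def predict_records(self, records):
        """Per-sequence (id, class label, score, flag) for raw sequences."""
        if not records:
            return []
        X, _ = featurize_matrix(records, self.selected_ggap)
        scores = self.decision_scores(X)
        neg, _, pos_label = SCHEMES[self.spec.scheme]
        out = []
        for rec, s in zip(records, scores):
            label = pos_label if s > 0 else neg
            min_g = min(g for _, g, _ in self.selected_ggap)
            flag = "short_sequence" if len(rec.residues) <= min_g + 1 else ""
            out.append({"id": rec.id, "label": label, "score": float(s), "flag": flag})
        return out

    def to_dict(self) -> dict:
        return {
            "format": "petmine-model-1",
            "scheme": self.spec.scheme,
            "method": self.spec.method,
            "standardize": self.spec.standardize,
            "seed": self.spec.seed,
            "selected_ggap": [list(d) for d in self.selected_ggap],
            "feature_names": self.feature_names,
            "kept_idx": list(map(int, self.kept_idx)),
            "mean": self.mean,
            "sd": self.sd,
            "best_params": self.best_params,
            "params": self.params,
            "n_per_class": self.n_per_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        if d.get("format") != "petmine-model-1":
            raise ConfigError("unrecognized model file format")
        spec = ClassifierSpec(scheme=d["scheme"], method=d["method"],
                              standardize=d["standardize"], seed=d["seed"])
        return cls(
            spec=spec,
            selected_ggap=[tuple(x) for x in d["selected_ggap"]],
            feature_names=d["feature_names"],
            kept_idx=d["kept_idx"],
            mean=d["mean"],
            sd=d["sd"],
            best_params=d["best_params"],
            params=d["params"],
            n_per_class=d.get("n_per_class", {}),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fit_one(spec: ClassifierSpec, params: dict, X: np.ndarray, y: np.ndarray):
    est = _make_estimator(spec.method, params, spec.seed)
    est.fit(X, y)
    return est


def train_classifier(spec: ClassifierSpec, train: LabeledDataset,
                     tune: LabeledDataset) -> TrainedModel:
    """Grid-search on the tune split, refit-free (tune-best model returned).

    Features are standardized with train-set statistics (for the methods
    that standardize); zero-variance features are dropped with a warning.
    Ties in tuning accuracy resolve to the earlier grid point.
    """
    Xtr, ytr, _, _ = binarize(train, spec.scheme)
    Xtu, ytu, _, _ = binarize(tune, spec.scheme)
    sd_all = Xtr.std(axis=0)
    kept = [int(j) for j in range(Xtr.shape[1]) if sd_all[j] > 0]
    if len(kept) < Xtr.shape[1]:
        warnings.warn(f"dropping {Xtr.shape[1] - len(kept)} zero-variance features")
    Xtr = Xtr[:, kept]
    Xtu = Xtu[:, kept]
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    if spec.standardize:
        Xtr = (Xtr - mean) / sd
        Xtu = (Xtu - mean) / sd
    best = None
    for params in spec.grid:
        est = _fit_one(spec, params, Xtr, ytr)
        native = _extract_params(spec.method, est, Xtr, ytr)
        scores = _native_scores(spec.method, native, Xtu)
        acc = float(((scores > 0).astype(int) == ytu).mean())
        if best is None or acc > best[0]:
            best = (acc, params, native)
    acc, params, native = best
    names = train.feature_names or feature_names()
    return TrainedModel(
        spec=spec,
        selected_ggap=_ggap_from_names(names),
        feature_names=names,
        kept_idx=kept,
        mean=mean.tolist(),
        sd=sd.tolist(),
        best_params=params,
        params=native,
        n_per_class={"0": int((ytr == 0).sum()), "1": int((ytr == 1).sum())},
    )


def _ggap_from_names(names) -> list:
    out = []
    for n in names:
        if n.startswith("ggap_"):
            a, g, b = n[len("ggap_"):].split("|")
            out.append((a, int(g), b))
    return out


# --- evaluation -------------------------------------------------------------

def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Accuracy, recall (TPR), specificity (TNR) and MCC from a confusion matrix."""
    n = tp + fp + fn + tn
    acc = (tp + tn) / n if n else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    return {"accuracy": acc, "recall": recall, "specificity": spec, "mcc": float(mcc)}


@dataclass
class EvalMetrics:
    per_fold: list                  # list of binary_metrics dicts
    accuracy: float
    recall: float
    specificity: float
    mcc: float

    @classmethod
    def from_folds(cls, folds: list) -> "EvalMetrics":
        return cls(
            per_fold=folds,
            accuracy=float(np.mean([f["accuracy"] for f in folds])),
            recall=float(np.mean([f["recall"] for f in folds])),
            specificity=float(np.mean([f["specificity"] for f in folds])),
            mcc=float(np.mean([f["mcc"] for f in folds])),
        )


def cross_validate(spec: ClassifierSpec, dataset: LabeledDataset,
                   folds: int = 5, seed: int = 0) -> EvalMetrics:
    """Stratified k-fold CV (cluster-respecting when clusters are attached).

    Each fold trains the method at its first (default) grid point; grid
    tuning proper uses a separate tune split via :func:`train_classifier`.
    """
    if folds < 2:
        raise ConfigError("need at least 2 folds")
    X, y, _, cl = binarize(dataset, spec.scheme)
    if cl is not None:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y, groups=cl)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    fold_metrics = []
    for train_idx, test_idx in split:
        ytr, yte = y[train_idx], y[test_idx]
        if len(set(ytr.tolist())) < 2 or len(set(yte.tolist())) < 2:
            raise EvaluationError("stratification error: a fold lacks one class")
        Xtr, Xte = X[train_idx], X[test_idx]
        sd_all = Xtr.std(axis=0)
        kept = sd_all > 0
        Xtr, Xte = Xtr[:, kept], Xte[:, kept]
        if spec.standardize:
            mean, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            Xtr = (Xtr - mean) / sd
            Xte = (Xte - mean) / sd
        est = _fit_one(spec, spec.grid[0], Xtr, ytr)
        native = _extract_params(spec.method, est, Xtr, ytr)
        pred = (_native_scores(spec.method, native, Xte) > 0).astype(int)
        tp = int(((pred == 1) & (yte == 1)).sum())
        fp = int(((pred == 1) & (yte == 0)).sum())
        fn = int(((pred == 0) & (yte == 1)).sum())
        tn = int(((pred == 0) & (yte == 0)).sum())
        fold_metrics.append(binary_metrics(tp, fp, fn, tn))
    return EvalMetrics.from_folds(fold_metrics)


def predict_thermophilicity(model: TrainedModel, records) -> list:
    """Deterministic class + score for each sequence under a trained model."""
    return model.predict_records(list(records))
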