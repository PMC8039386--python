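"""Distance-statistic screening of gastric-wall layer proportions.

A patient's five-layer proportion vector x is compared against a
standard vector s (the cohort average of normal walls) through the
distance

    d = sqrt( (x1-s1)^2 + (x2-s2)^2 + (x3-s3)^2 + (x4-s4)^2 )

which deliberately uses only the first four components -- the statistic
is defined this way and is kept unchanged (a flag restores
the fifth term for sensitivity analyses).  Large d flags an abnormal
wall.  The decision threshold is fitted on a stratified 70/30 split by
maximising training accuracy under the rule "abnormal iff d >=
threshold" (ties at the threshold go to abnormal: screening favours
sensitivity), then applied unchanged to the test set, where the usual
confusion-matrix metrics and the ROC AUC of the d score are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import GastrolayerError, NoWallDetectedError, UnstratifiableROIError

#: Reference standard vector (normal-wall layer proportions).  As
#: tabulated it sums to 0.999 -- it is used without renormalisation.
STANDARD_VECTOR = (0.278, 0.133, 0.154, 0.154, 0.280)

ABNORMAL, NORMAL = "abnormal", "normal"


def _as5(v, name):
    v = np.asarray(v, dtype=float)
    if v.shape != (5,):
        raise GastrolayerError(f"{name} must be a 5-vector")
    return v


def estimate_standard_vector(cohort_x) -> np.ndarray:
    """Component-wise mean of proportion vectors; not renormalised."""
    xs = [_as5(x, "x") for x in cohort_x]
    if not xs:
        raise GastrolayerError("cannot average an empty cohort")
    return np.mean(xs, axis=0)


def distance(x, s, include_fifth_term: bool = False) -> float:
    """The screening distance d between x and the standard vector s."""
    x = _as5(x, "x")
    s = _as5(s, "s")
    k = 5 if include_fifth_term else 4
    return float(math.sqrt(((x[:k] - s[:k]) ** 2).sum()))


def split_cohort(records, train_fraction: float = 0.7, seed: int = 0,
                 label_of=lambda r: r.label):
    """Stratified random train/test split, reproducible under ``seed``.

    Per-class training quotas are allocated by largest remainder so the
    overall training size is round(train_fraction * n).  Errors if any
    class would be missing from either side.
    """
    records = list(records)
    if not 0 < train_fraction < 1:
        raise GastrolayerError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list] = {}
    for r in records:
        by_class.setdefault(label_of(r), []).append(r)

    n_total = len(records)
    target = int(np.floor(train_fraction * n_total + 0.5))
    labels = sorted(by_class)
    quotas = {lbl: int(np.floor(train_fraction * len(by_class[lbl]))) for lbl in labels}
    remainders = sorted(
        labels,
        key=lambda lbl: (train_fraction * len(by_class[lbl])) % 1.0,
        reverse=True,
    )
    i = 0
    while sum(quotas.values()) < target and i < len(remainders):
        quotas[remainders[i]] += 1
        i += 1

    train, test = [], []
    for lbl in labels:
        group = by_class[lbl]
        k = quotas[lbl]
        if k < 1 or k >= len(group):
            raise GastrolayerError(
                f"class {lbl!r} would be absent from train or test at this fraction"
            )
        order = rng.permutation(len(group))
        train.extend(group[j] for j in order[:k])
        test.extend(group[j] for j in order[k:])
    return train, test


def fit_threshold(train_d, train_labels) -> float:
    """Training-accuracy-optimal threshold for "abnormal iff d >= t".

    Candidates are midpoints between consecutive distinct sorted d
    values plus one candidate below the minimum (everything abnormal)
    and one above the maximum (everything normal); ties in accuracy are
    broken toward the smaller threshold, i.e. higher sensitivity.
    """
    d = np.asarray(train_d, dtype=float)
    y = np.asarray([1 if lbl == ABNORMAL else 0 for lbl in train_labels])
    if len(d) != len(y) or len(d) == 0:
        raise GastrolayerError("d values and labels must be equally many and nonempty")
    if y.min() == y.max():
        raise GastrolayerError("both classes must be present to fit a threshold")
    uniq = np.unique(d)
    candidates = np.concatenate([[max(0.0, uniq[0] - 1.0)],
                                 0.5 * (uniq[1:] + uniq[:-1]),
                                 [uniq[-1] + 1.0]])
    best_t, best_acc = None, -1.0
    for t in candidates:
        acc = float(((d >= t).astype(int) == y).mean())
        if acc > best_acc:  # candidates ascend, so ties keep the smaller t
            best_acc, best_t = acc, float(t)
    return best_t


@dataclass(frozen=True)
class ScreeningModel:
    s: tuple[float, ...] = STANDARD_VECTOR
    threshold: float = 0.0
    include_fifth_term: bool = False

    def __post_init__(self):
        if self.threshold < 0:
            raise GastrolayerError("threshold must be nonnegative")

    def d(self, x) -> float:
        return distance(x, self.s, self.include_fifth_term)

    def classify_x(self, x) -> str:
        return classify(self.d(x), self)


def classify(d: float, model: ScreeningModel) -> str:
    """Abnormal iff d >= threshold (boundary goes to abnormal)."""
    return ABNORMAL if d >= model.threshold else NORMAL


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @staticmethod
    def from_predictions(pred_labels, true_labels) -> "ConfusionCounts":
        pairs = list(zip(pred_labels, true_labels))
        return ConfusionCounts(
            tp=sum(p == ABNORMAL and t == ABNORMAL for p, t in pairs),
            tn=sum(p == NORMAL and t == NORMAL for p, t in pairs),
            fp=sum(p == ABNORMAL and t == NORMAL for p, t in pairs),
            fn=sum(p == NORMAL and t == ABNORMAL for p, t in pairs),
        )


def _ratio(num, den):
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> dict:
    """ACC, SENS, SPEC, PPV, NPV, MCC and F1 from a confusion table.

    Any metric with a zero denominator is reported as None (undefined),
    never silently as zero.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    total = tp + tn + fp + fn
    if total == 0:
        raise GastrolayerError("empty confusion table")
    acc = (tp + tn) / total
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else None
    f1 = None
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f1 = 2 * ppv * sens / (ppv + sens)
    return {"ACC": acc, "SENS": sens, "SPEC": spec, "PPV": ppv,
            "NPV": npv, "MCC": mcc, "F1": f1}


def roc_auc(d_values, labels) -> float:
    """AUC of the d score for the rule "abnormal iff d >= t".

    Trapezoidal area over the empirical operating points, equal to the
    Mann-Whitney probability with half credit for ties.
    """
    y = np.asarray([1 if lbl == ABNORMAL else 0 for lbl in labels])
    d = np.asarray(d_values, dtype=float)
    if len(y) == 0 or y.min() == y.max():
        raise GastrolayerError("both classes must be present to compute AUC")
    return float(roc_auc_score(y, d))


# ---------------------------------------------------------------------------
# End-to-end evaluation on a phantom cohort


@dataclass
class PipelineConfig:
    """Configuration of the full simulate -> detect -> SRAD -> stratify ->
    screen evaluation."""

    train_fraction: float = 0.7
    roi_margin: int = 10
    n_columns: int = 9
    min_valid_columns: int = 3
    srad_iterations: int = 100
    srad_time_step: float = 0.05
    srad_variant: str = "reciprocal"
    use_truth_masks: bool = True  # oracle ROI mode; False trains the U-net
    s_from: str = "train_normals"  # or "train_all"
    include_fifth_term: bool = False
    detector: "object | None" = None  # DetectorConfig when training
    seed: int = 0


@dataclass
class CaseResult:
    index: int
    label: str
    x: np.ndarray | None
    d: float | None = None
    prediction: str | None = None
    split: str | None = None
    excluded_reason: str | None = None


@dataclass
class PipelineReport:
    model: ScreeningModel
    metrics: dict
    auc: float
    cases: list[CaseResult] = field(default_factory=list)
    n_excluded: int = 0


def _extract_x(truth, cfg: PipelineConfig, mask: np.ndarray):
    from .detect import mask_to_roi
    from .srad import DiffusionParams, srad_filter
    from .stratify import aggregate_columns

    roi = mask_to_roi(mask, margin=cfg.roi_margin)
    crop = roi.crop(truth.image)
    mask_crop = roi.crop(mask.astype(bool))
    # the lumen above the wall inside the ROI is homogeneous speckle; use
    # the outer half of the top margin band as the q0 window so diffusion
    # bleeding across the wall edge never contaminates it
    win_h = max(3, min(cfg.roi_margin // 2, crop.shape[0] // 4))
    window = (0, win_h, 0, crop.shape[1])
    params = DiffusionParams(
        time_step=cfg.srad_time_step,
        n_iterations=cfg.srad_iterations,
        variant=cfg.srad_variant,
        homog_window=window,
    )
    filtered = srad_filter(crop, params)
    return aggregate_columns(
        filtered,
        n_columns=cfg.n_columns,
        mask=mask_crop,
        min_valid=cfg.min_valid_columns,
    )


def evaluate_pipeline(cohort, cfg: PipelineConfig | None = None) -> PipelineReport:
    """Run the whole screening chain on a labelled phantom cohort.

    Wall masks come from the ground truth (oracle mode, default) or
    from a U-net trained on the training split; every wall is then SRAD
    filtered, stratified into x, reduced to d against the standard
    vector estimated from training normals, thresholded on the training
    split and scored on the test split.  Unstratifiable images are
    excluded and counted.
    """
    cfg = cfg or PipelineConfig()
    cohort = list(cohort)
    train_idx, test_idx = split_cohort(
        range(len(cohort)), cfg.train_fraction, seed=cfg.seed,
        label_of=lambda i: cohort[i].label,
    )
    split_of = {i: "train" for i in train_idx}
    split_of.update({i: "test" for i in test_idx})

    masks: dict[int, np.ndarray] = {}
    if cfg.use_truth_masks:
        for i, truth in enumerate(cohort):
            masks[i] = truth.wall_mask
    else:
        from .detect import DetectorConfig, predict_mask, train_detector

        det_cfg = cfg.detector or DetectorConfig(seed=cfg.seed)
        model = train_detector(
            [cohort[i].image for i in train_idx],
            [cohort[i].wall_mask for i in train_idx],
            det_cfg,
        )
        for i, truth in enumerate(cohort):
            masks[i] = predict_mask(model, truth.image)

    cases: list[CaseResult] = []
    for i, truth in enumerate(cohort):
        try:
            x = _extract_x(truth, cfg, masks[i])
            cases.append(CaseResult(i, truth.label, x, split=split_of[i]))
        except (UnstratifiableROIError, NoWallDetectedError) as err:
            cases.append(CaseResult(i, truth.label, None, split=split_of[i],
                                    excluded_reason=str(err)))

    usable = [c for c in cases if c.x is not None]
    train_cases = [c for c in usable if c.split == "train"]
    test_cases = [c for c in usable if c.split == "test"]
    if cfg.s_from == "train_normals":
        basis = [c.x for c in train_cases if c.label == NORMAL]
    else:
        basis = [c.x for c in train_cases]
    s = estimate_standard_vector(basis)

    for c in usable:
        c.d = distance(c.x, s, cfg.include_fifth_term)
    threshold = fit_threshold([c.d for c in train_cases], [c.label for c in train_cases])
    model = ScreeningModel(s=tuple(s), threshold=threshold,
                           include_fifth_term=cfg.include_fifth_term)
    for c in usable:
        c.prediction = classify(c.d, model)

    counts = ConfusionCounts.from_predictions(
        [c.prediction for c in test_cases], [c.label for c in test_cases]
    )
    metrics = compute_metrics(counts)
    auc = roc_auc([c.d for c in test_cases], [c.label for c in test_cases])
    return PipelineReport(
        model=model,
        metrics={**metrics, "AUC": auc},
        auc=auc,
        cases=cases,
        n_excluded=sum(c.x is None for c in cases),
    )
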