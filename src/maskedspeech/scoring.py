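"""Consonant-confusion scoring: accuracy, feature transmission, RAU.

The task is closed-set identification of 12 consonants in CV syllables
(/b s d h k m n p sh t v z/ + /i/).  Each consonant carries three
articulatory feature values:

* voicing: voiced {b d m n v z} vs unvoiced {s h k t p sh};
* manner: stop {b d p t k}, fricative {v z s h sh}, nasal {m n};
* place: front {p b m v}, middle {s z t d n}, back {sh k h}.

"Feature transmission" is the proportion of trials whose response shares
the target's value on that feature; it is bounded below by overall accuracy
(a correct consonant gets every feature correct).  Proportions are mapped
to rationalized arcsine units (RAU; Studebaker's linear-rescaled two-term
arcsine transform) for linear modeling: RAU(0.5) = 50, and scores extend a
little beyond 0 and 100 so near-ceiling data stay approximately
homoscedastic.

The IPA consonant /ʃ/ is serialized as ``"sh"`` throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONSONANTS",
    "GROUPS",
    "MODALITIES",
    "MASKS",
    "FeatureScheme",
    "ConfusionMatrix",
    "tabulate_confusions",
    "score_confusion",
    "rau",
    "rau_from_proportion",
    "proportion_from_rau",
    "chance_levels",
    "score_table",
    "audiovisual_benefit",
    "validate_trials",
]

CONSONANTS = ("b", "s", "d", "h", "k", "m", "n", "p", "sh", "t", "v", "z")
GROUPS = ("CHL", "CNH", "ANH")
MODALITIES = ("AO", "AV", "VO")
MASKS = ("none", "hospital", "fabric", "communicator", "clearmask")

#: Columns a trial table must carry.
TRIAL_COLUMNS = (
    "subject_id", "group", "age", "modality", "mask", "snr_db", "run",
    "token", "target", "response",
)


def _default_voicing() -> dict[str, str]:
    return {c: ("voiced" if c in {"b", "d", "m", "n", "v", "z"} else "unvoiced")
            for c in CONSONANTS}


def _default_manner() -> dict[str, str]:
    m = {}
    for c in CONSONANTS:
        if c in {"b", "d", "p", "t", "k"}:
            m[c] = "stop"
        elif c in {"v", "z", "s", "h", "sh"}:
            m[c] = "fricative"
        else:
            m[c] = "nasal"
    return m


def _default_place() -> dict[str, str]:
    p = {}
    for c in CONSONANTS:
        if c in {"p", "b", "m", "v"}:
            p[c] = "front"
        elif c in {"s", "z", "t", "d", "n"}:
            p[c] = "middle"
        else:
            p[c] = "back"
    return p


@dataclass(frozen=True)
class FeatureScheme:
    """Assignment of voicing / manner / place values to the 12 consonants."""

    consonants: tuple[str, ...] = CONSONANTS
    voicing: dict[str, str] = field(default_factory=_default_voicing)
    manner: dict[str, str] = field(default_factory=_default_manner)
    place: dict[str, str] = field(default_factory=_default_place)

    @property
    def features(self) -> dict[str, dict[str, str]]:
        return {"voicing": self.voicing, "manner": self.manner, "place": self.place}

    def __post_init__(self) -> None:
        for name, mapping in self.features.items():
            missing = set(self.consonants) - set(mapping)
            if missing:
                raise ValueError(f"feature {name!r} misses consonants {missing}")


DEFAULT_SCHEME = FeatureScheme()


@dataclass
class ConfusionMatrix:
    """12x12 stimulus-response counts (rows = target, columns = response)."""

    counts: np.ndarray
    consonants: tuple[str, ...] = CONSONANTS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.consonants)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def presentations(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts, self.consonants)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.consonants),
                            columns=list(self.consonants))


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check a trial table's vocabulary; returns the table unchanged.

    Raises ``ValueError`` listing every offending row (0-based data row
    numbers) and its bad field.
    """
    errors = []
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise ValueError(f"trial table is missing column {col!r}")
    vocab = {"group": GROUPS, "modality": MODALITIES, "mask": MASKS,
             "target": CONSONANTS, "response": CONSONANTS}
    for col, allowed in vocab.items():
        bad = ~trials[col].isin(allowed)
        for i in trials.index[bad]:
            errors.append(f"row {i}: {col}={trials.at[i, col]!r} not in {allowed}")
    vo_masked = (trials["modality"] == "VO") & (trials["mask"] != "none")
    for i in trials.index[vo_masked]:
        errors.append(
            f"row {i}: visual-only trials are run without a mask "
            f"(mask={trials.at[i, 'mask']!r})"
        )
    if errors:
        raise ValueError("invalid trial table:\n" + "\n".join(errors))
    return trials


def tabulate_confusions(
    trials: pd.DataFrame,
    by: tuple[str, ...] = ("subject_id", "mask", "modality"),
    drop_incomplete: bool = False,
    block_size: int = 36,
) -> dict[tuple, ConfusionMatrix]:
    """Confusion matrix per grouping cell.

    With ``drop_incomplete`` set, cells whose trial count is not a multiple
    of the block size (36 = 12 consonants x 3 tokens) are excluded, matching
    the conventional treatment of abandoned runs.
    """
    validate_trials(trials)
    idx = {c: i for i, c in enumerate(CONSONANTS)}
    out: dict[tuple, ConfusionMatrix] = {}
    if len(trials) == 0:
        return out
    for key, sub in trials.groupby(list(by), observed=True, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if drop_incomplete and len(sub) % block_size != 0:
            continue
        counts = np.zeros((12, 12), dtype=np.int64)
        rows = sub["target"].map(idx).to_numpy()
        cols = sub["response"].map(idx).to_numpy()
        np.add.at(counts, (rows, cols), 1)
        out[key] = ConfusionMatrix(counts)
    return out


def score_confusion(
    cm: ConfusionMatrix, scheme: FeatureScheme = DEFAULT_SCHEME
) -> dict[str, float]:
    """Accuracy and per-feature transmission proportions of one matrix."""
    total = cm.total
    if total == 0:
        raise ValueError("cannot score an all-zero confusion matrix")
    scores = {"accuracy": float(np.trace(cm.counts)) / total}
    for name, mapping in scheme.features.items():
        values = np.array([mapping[c] for c in cm.consonants])
        same = values[:, None] == values[None, :]
        scores[name] = float(cm.counts[same].sum()) / total
    return scores


def rau(correct: int, total: int) -> float:
    """Rationalized arcsine unit from pooled counts.

    theta = arcsin sqrt(X/(N+1)) + arcsin sqrt((X+1)/(N+1));
    RAU = (146/pi) * theta - 23.  Maps 0..N onto about -15.3..115.3 (for
    N=36) with RAU(N/2, N) = 50 exactly.
    """
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if not 0 <= correct <= total:
        raise ValueError(f"correct={correct} outside [0, {total}]")
    theta = math.asin(math.sqrt(correct / (total + 1))) + math.asin(
        math.sqrt((correct + 1) / (total + 1))
    )
    return (146.0 / math.pi) * theta - 23.0


def rau_from_proportion(p) -> np.ndarray | float:
    """Continuous RAU of a true proportion: (146/pi)*2*arcsin(sqrt(p)) - 23."""
    p = np.asarray(p, dtype=float)
    out = (146.0 / math.pi) * 2.0 * np.arcsin(np.sqrt(p)) - 23.0
    return float(out) if out.ndim == 0 else out


def proportion_from_rau(r) -> np.ndarray | float:
    """Inverse of :func:`rau_from_proportion`, clipped to [0, 1]."""
    r = np.asarray(r, dtype=float)
    theta = np.clip((r + 23.0) * math.pi / 146.0 / 2.0, 0.0, math.pi / 2)
    out = np.square(np.sin(theta))
    return float(out) if out.ndim == 0 else out


def chance_levels(scheme: FeatureScheme = DEFAULT_SCHEME) -> dict[str, float]:
    """Expected scores of a uniform random responder under uniform targets.

    Accuracy is 1/K.  Each feature's chance is ``sum (n_c / K)^2`` over its
    categories: the probability that an independent uniform response lands
    in the target's category.
    """
    k = len(scheme.consonants)
    levels = {"accuracy": 1.0 / k}
    for name, mapping in scheme.features.items():
        sizes = pd.Series(mapping).value_counts()
        levels[name] = float(np.sum((sizes / k) ** 2))
    return levels


def score_table(
    trials: pd.DataFrame,
    by: tuple[str, ...] = ("subject_id", "group", "mask", "modality", "snr_db"),
    scheme: FeatureScheme = DEFAULT_SCHEME,
    drop_incomplete: bool = False,
) -> pd.DataFrame:
    """Per-cell score table: counts, proportion correct, RAU, transmissions.

    Counts are pooled over runs within each cell before scoring (RAU is
    computed from the pooled counts).  Feature-transmission proportions are
    also reported in RAU for use in the feature-level models.
    """
    cms = tabulate_confusions(trials, by=by, drop_incomplete=drop_incomplete)
    rows = []
    for key, cm in cms.items():
        scores = score_confusion(cm, scheme)
        n = cm.total
        n_correct = int(np.trace(cm.counts))
        row = dict(zip(by, key))
        row.update(
            n_trials=n,
            n_correct=n_correct,
            proportion=scores["accuracy"],
            rau=rau(n_correct, n),
        )
        for feat in ("voicing", "manner", "place"):
            row[feat] = scores[feat]
            row[f"{feat}_rau"] = rau(int(round(scores[feat] * n)), n)
        rows.append(row)
    return pd.DataFrame(rows)


def audiovisual_benefit(
    scores: pd.DataFrame,
    keys: tuple[str, ...] = ("subject_id", "group", "mask", "snr_db"),
) -> pd.DataFrame:
    """AV minus AO RAU per matched cell.

    Cells with only one modality present are returned with a NaN benefit
    and ``matched=False`` rather than silently dropped.
    """
    wide = scores.pivot_table(index=list(keys), columns="modality",
                              values="rau", aggfunc="mean")
    for col in ("AO", "AV"):
        if col not in wide:
            wide[col] = np.nan
    out = wide.reset_index()
    out["benefit_rau"] = out["AV"] - out["AO"]
    out["matched"] = out["AV"].notna() & out["AO"].notna()
    return out[list(keys) + ["AO", "AV", "benefit_rau", "matched"]]
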