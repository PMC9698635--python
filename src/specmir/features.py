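"""Intrinsic sequence features of miRNA loci and SS-vs-NSS statistics.

Features per locus: normalized minimum free energy of the hairpin
(NMFE = MFE / hairpin length, kcal/mol per nt), AU content of the mature
and of the hairpin, the 5' first base of the mature, and the mature and
hairpin lengths.  Group contrasts use Welch's unequal-variance two-sample
t-test (the SS and NSS groups differ greatly in size, so a pooled-variance
test is inappropriate).  Relative feature importance is ranked with a
gradient-boosted tree classifier (learning rate 1, depth 2, 50 rounds,
binary logistic objective) using gain-based importances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MiRNALocus
from . import folding

FIRST_BASES = ("A", "C", "G", "U")
NUMERIC_FEATURES = ("nmfe", "au_mature", "au_hairpin", "len_mature", "len_hairpin")


@dataclass(frozen=True)
class FeatureVector:
    locus_id: str
    nmfe: float | None
    au_mature: float
    au_hairpin: float
    first_base: str
    len_mature: int
    len_hairpin: int
    label: str | None = None


def compute_nmfe(hairpin: str) -> float:
    """MFE of the hairpin divided by its length (kcal/mol per nt, <= 0)."""
    if len(hairpin) < 40:
        raise ValueError("hairpin shorter than 40 nt")
    _, mfe = folding.fold(hairpin)
    return mfe / len(hairpin)


def au_content(seq: str) -> float:
    return (seq.count("A") + seq.count("U")) / len(seq)


def compute_features(loci: list[MiRNALocus],
                     calls=None,
                     with_nmfe: bool = True) -> list[FeatureVector]:
    """One feature vector per locus; ``calls`` (locus-level) supply labels."""
    label_of = {}
    if calls is not None:
        label_of = {c.subject: c.label for c in calls if c.level == "locus"}
    out = []
    for l in loci:
        out.append(FeatureVector(
            locus_id=l.locus_id,
            nmfe=compute_nmfe(l.hairpin_seq) if with_nmfe else None,
            au_mature=au_content(l.mature_seq),
            au_hairpin=au_content(l.hairpin_seq),
            first_base=l.mature_seq[0],
            len_mature=len(l.mature_seq),
            len_hairpin=len(l.hairpin_seq),
            label=label_of.get(l.locus_id),
        ))
    return out


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    df = pd.DataFrame([vars(v) for v in vectors]).set_index("locus_id")
    return df


def compare_groups(values_ss, values_nss) -> tuple[float, float, tuple[float, float]]:
    """Welch two-sample t-test, two-tailed.

    Returns ``(t, p, (mean_ss, mean_nss))``.  Two zero-variance groups
    with equal means give t = 0, p = 1 by convention.
    """
    a = np.asarray(values_ss, dtype=float)
    b = np.asarray(values_nss, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0, (float(a.mean()), float(b.mean()))
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), (float(a.mean()), float(b.mean()))


def feature_stats(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Welch tests for every numeric feature, SS vs NSS."""
    df = features_to_frame(vectors)
    rows = []
    for feat in NUMERIC_FEATURES:
        ss = df.loc[df.label == "SS", feat].dropna()
        nss = df.loc[df.label == "NSS", feat].dropna()
        t, p, (m_ss, m_nss) = compare_groups(ss, nss)
        rows.append({"feature": feat, "mean_ss": m_ss, "mean_nss": m_nss,
                     "t": t, "p": p})
    return pd.DataFrame(rows)


def encode_design_matrix(vectors: list[FeatureVector]) -> tuple[pd.DataFrame, np.ndarray]:
    """Numeric features + one-hot 5' first base; labels SS=1, NSS=0."""
    df = features_to_frame(vectors)
    if df.label.isna().any():
        raise ValueError("all vectors must be labeled for the importance model")
    X = df[list(NUMERIC_FEATURES)].copy()
    for base in FIRST_BASES:
        X[f"first_base_{base}"] = (df.first_base == base).astype(int)
    y = (df.label == "SS").to_numpy(dtype=int)
    return X, y


def rank_feature_importance(vectors: list[FeatureVector], *,
                            learning_rate: float = 1.0, max_depth: int = 2,
                            rounds: int = 50, holdout_frac: float = 0.25,
                            seed: int = 0) -> tuple[list[tuple[str, float]], float]:
    """Gain-based feature ranking from a gradient-boosted tree classifier.

    Returns ``(ranking, holdout_accuracy)`` where ranking is a list of
    (feature, gain) sorted by decreasing gain; features the model never
    split on get gain 0.  Deterministic under ``seed``.
    """
    import xgboost as xgb
    from sklearn.model_selection import train_test_split

    X, y = encode_design_matrix(vectors)
    if len(np.unique(y)) < 2:
        raise ValueError("both SS and NSS classes are required")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_frac, random_state=seed, stratify=y)
    model = xgb.XGBClassifier(
        learning_rate=learning_rate, max_depth=max_depth, n_estimators=rounds,
        objective="binary:logistic", random_state=seed, n_jobs=1,
        tree_method="exact", eval_metric="logloss")
    model.fit(X_tr, y_tr)
    accuracy = float((model.predict(X_te) == y_te).mean())
    gains = model.get_booster().get_score(importance_type="gain")
    ranking = sorted(((f, gains.get(f, 0.0)) for f in X.columns),
                     key=lambda kv: (-kv[1], kv[0]))
    return ranking, accuracy
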