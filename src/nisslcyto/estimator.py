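"""Scikit-learn-compatible wrapper around the rule classifier.

The decision rules have no free parameters to learn, so ``fit`` only
validates the input schema and records the fitted attributes; ``predict``
maps rows of categorical cytological features to cell-type labels.  The
estimator supports ``get_params``/``set_params``/``clone`` and composes
with sklearn pipelines operating on DataFrames of string-valued features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .profiles import REQUIRED_FIELDS, validate_profile
from .rules import classify
from .vocab import FINE_LABELS, RATING_LABELS


class RuleBasedCytologyClassifier(ClassifierMixin, BaseEstimator):
    """Deterministic rule-based classifier over cytological feature rows.

    Parameters
    ----------
    level : {"rating", "fine"}
        Predict the five-way rating label or the six-way fine label.
    tiebreak : bool
        Resolve balanced-evidence profiles deterministically (default) or
        mark them as flagged in :meth:`classify_frame`.

    Examples
    --------
    >>> import pandas as pd
    >>> from nisslcyto.profiles import PROTOTYPES
    >>> X = pd.DataFrame([p.to_record() for p in PROTOTYPES.values()])
    >>> RuleBasedCytologyClassifier().fit(X).predict(X)[:2]
    array(['neuron', 'neuron'], dtype='<U15')
    """

    def __init__(self, level: str = "rating", tiebreak: bool = True):
        self.level = level
        self.tiebreak = tiebreak

    def _validate_X(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        missing = [f for f in REQUIRED_FIELDS if f not in X.columns]
        if missing:
            raise ValueError(f"X is missing required feature columns: {missing}")
        return X

    def fit(self, X, y=None):
        """Validate the schema; the rules themselves are fixed."""
        if self.level not in ("rating", "fine"):
            raise ValueError(f"level must be 'rating' or 'fine', got {self.level!r}")
        X = self._validate_X(X)
        self.classes_ = np.asarray(
            RATING_LABELS if self.level == "rating" else FINE_LABELS
        )
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "classes_"):
            raise AttributeError(
                "This RuleBasedCytologyClassifier instance is not fitted yet; "
                "call 'fit' first."
            )

    def classify_frame(self, X) -> pd.DataFrame:
        """Full per-row results: fine/rating labels, path, ambiguity."""
        self._check_fitted()
        X = self._validate_X(X)
        rows = []
        for record in X.to_dict(orient="records"):
            result = classify(validate_profile(record), tiebreak=self.tiebreak)
            rows.append(
                {
                    "fine": result.label.fine,
                    "rating": result.label.rating,
                    "question_path": ">".join(result.question_path),
                    "ambiguity": result.ambiguity,
                    "candidates": ";".join(sorted(result.candidates)),
                    "supporting_features": ";".join(result.supporting_features),
                }
            )
        return pd.DataFrame(rows, index=X.index)

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        frame = self.classify_frame(X)
        return frame["rating" if self.level == "rating" else "fine"].to_numpy(
            dtype="<U15"
        )

    def score(self, X, y, sample_weight=None) -> float:
        return float(np.average(self.predict(X) == np.asarray(y), weights=sample_weight))
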