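"""Beat classification: per-cumulant Hermite features, 1-NN banks, fusion.

Pipeline: a beat's 2nd/3rd/4th-order cumulant slices are each modelled with
26 Hermite coefficients (GA-optimised width); each coefficient vector is
classified by a 1-nearest-neighbour rule against its own training bank
(Euclidean distance); the three labels are fused by majority vote, falling
back to the 3rd-order cumulant's label when all three disagree (the
3rd-order classifier is empirically the most reliable single order).

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
compose with sklearn model selection.  ``SignalHermite1NN`` is the
raw-signal reference method: the same Hermite model fitted to the beat
itself instead of its cumulants — accurate on clean data but sensitive to
baseline shifts and noise, which is precisely what the cumulant front end
removes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .beats import Beat, N_SAMPLES
from .cumulants import center, cumulant_set
from .hermite import DEFAULT_ORDER, GAConfig, model_cumulant

ORDERS = (2, 3, 4)
#: position of the 3rd-order cumulant label in a per-order label triple
_FALLBACK_SLOT = 1


@dataclass(frozen=True)
class Prediction:
    """Per-order labels (orders 2, 3, 4), the fused label, and how many of
    the three per-order labels agree with the winner (3, 2 or 1)."""

    per_order_labels: tuple[str, str, str]
    fused: str
    agreement: int


def fuse(labels) -> str:
    """Majority vote over the (order-2, order-3, order-4) label triple;
    when all three differ, the 3rd-order cumulant's label wins."""
    l2, l3, l4 = labels
    if l2 == l3 or l2 == l4:
        return l2
    if l3 == l4:
        return l3
    return l3  # three-way disagreement: rely on the 3rd-order cumulant


def nn_label(query, bank_features: np.ndarray, bank_labels) -> str:
    """Label of the Euclidean-nearest training vector; exact ties go to the
    lowest training index."""
    query = np.asarray(query, dtype=float)
    bank_features = np.asarray(bank_features, dtype=float)
    if bank_features.ndim != 2 or len(bank_features) == 0:
        raise ValueError("training bank must be a nonempty 2-D array")
    if query.shape != (bank_features.shape[1],):
        raise ValueError("query dimension does not match the training bank")
    d2 = ((bank_features - query) ** 2).sum(axis=1)
    return bank_labels[int(np.argmin(d2))]


def _beats_to_matrix(X) -> np.ndarray:
    """Accept a list of Beats or an (n, 201) array; return waveforms with
    any symbolic baseline kept out (it is removed by centering anyway)."""
    if len(X) > 0 and isinstance(X[0], Beat):
        return np.stack([b.waveform for b in X])
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != N_SAMPLES:
        raise ValueError(f"expected (n, {N_SAMPLES}) beat matrix, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("beat samples must be finite")
    return X


def _labels_of(X, y):
    if y is not None:
        return np.asarray(y, dtype=object)
    if len(X) > 0 and isinstance(X[0], Beat):
        labels = [b.label for b in X]
        if all(l is not None for l in labels):
            return np.asarray(labels, dtype=object)
    raise ValueError("labels are required: pass y or labelled Beats")


def _ga_seed(random_state: int, order: int) -> int:
    # one GA seed per cumulant order, shared across beats, so features never
    # depend on a beat's position in the dataset
    return (int(random_state) * 1_000_003 + 7919 * order) % (2**31)


class CumulantHermite1NN(ClassifierMixin, BaseEstimator):
    """Fused 1-NN classifier on Hermite models of beat cumulant slices.

    Parameters
    ----------
    n_coefficients : int, default 26
        Hermite model order N per cumulant (26 coefficients each).
    include_sigma : bool, default False
        Append the fitted width to each feature vector.  Off by default:
        sigma's scale differs from the coefficients' and would dominate
        the Euclidean distance.
    standardize : bool, default False
        Z-score features per dimension using training statistics.
    ga_config : GAConfig or None
        Width-search settings; ``None`` uses the defaults (population 10,
        mutation probability 0.9, sigma in [2, 60] samples).
    random_state : int, default 0
        Seeds the GA width searches (one derived seed per cumulant order).

    Attributes
    ----------
    classes_ : ndarray of unique training labels
    banks_ : dict mapping cumulant order -> (n_train, n_features) array
    bank_labels_ : ndarray of training labels shared by the three banks
    """

    def __init__(self, n_coefficients: int = DEFAULT_ORDER,
                 include_sigma: bool = False, standardize: bool = False,
                 ga_config: GAConfig | None = None, random_state: int = 0):
        self.n_coefficients = n_coefficients
        self.include_sigma = include_sigma
        self.standardize = standardize
        self.ga_config = ga_config
        self.random_state = random_state

    # -- feature extraction -------------------------------------------------

    def _config_for(self, order: int) -> GAConfig:
        base = self.ga_config if self.ga_config is not None else GAConfig()
        return replace(base, seed=_ga_seed(self.random_state, order))

    def _featurize_one(self, waveform: np.ndarray) -> dict[int, np.ndarray]:
        cums = cumulant_set(Beat(waveform=waveform))
        feats = {}
        for order, cv in zip(ORDERS, cums):
            f = model_cumulant(cv, self.n_coefficients, self._config_for(order))
            vec = f.coefficients
            if self.include_sigma:
                vec = np.append(vec, f.sigma)
            feats[order] = vec
        return feats

    def featurize(self, X) -> dict[int, np.ndarray]:
        """Feature banks for a batch of beats: order -> (n, n_features)."""
        mat = _beats_to_matrix(X)
        rows = [self._featurize_one(w) for w in mat]
        return {o: np.stack([r[o] for r in rows]) for o in ORDERS}

    # -- sklearn protocol ----------------------------------------------------

    def fit(self, X, y=None):
        labels = _labels_of(X, y)
        feats = self.featurize(X)
        if len(labels) != len(next(iter(feats.values()))):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(labels.astype(str))
        from .beats import CLASSES
        missing = set(CLASSES) - set(self.classes_)
        if missing and set(self.classes_) <= set(CLASSES):
            warnings.warn(f"training set has no beats for classes: {sorted(missing)}",
                          stacklevel=2)
        self.bank_labels_ = labels
        if self.standardize:
            self.scalers_ = {
                o: (f.mean(axis=0), np.where(f.std(axis=0) > 0, f.std(axis=0), 1.0))
                for o, f in feats.items()
            }
            feats = {o: (f - self.scalers_[o][0]) / self.scalers_[o][1]
                     for o, f in feats.items()}
        self.banks_ = feats
        return self

    def _predict_full(self, X) -> list[Prediction]:
        check_is_fitted(self, "banks_")
        feats = self.featurize(X)
        if self.standardize:
            feats = {o: (f - self.scalers_[o][0]) / self.scalers_[o][1]
                     for o, f in feats.items()}
        preds = []
        for i in range(len(next(iter(feats.values())))):
            triple = tuple(
                nn_label(feats[o][i], self.banks_[o], self.bank_labels_)
                for o in ORDERS
            )
            fused = fuse(triple)
            preds.append(Prediction(per_order_labels=triple, fused=fused,
                                    agreement=sum(l == fused for l in triple)))
        return preds

    def predict(self, X) -> np.ndarray:
        """Fused class label per beat."""
        return np.asarray([p.fused for p in self._predict_full(X)], dtype=object)

    def predict_detail(self, X) -> list[Prediction]:
        """Full per-order + fused predictions (one Prediction per beat)."""
        return self._predict_full(X)

    def predict_per_order(self, X) -> dict[int, np.ndarray]:
        """Single-order 1-NN labels, one array per cumulant order."""
        preds = self._predict_full(X)
        return {o: np.asarray([p.per_order_labels[i] for p in preds], dtype=object)
                for i, o in enumerate(ORDERS)}


class SignalHermite1NN(ClassifierMixin, BaseEstimator):
    """Reference method: 1-NN on Hermite coefficients of the raw beat.

    Operates on the materialised samples (waveform + baseline) with no
    centering and no cumulant stage, so it inherits the raw signal's
    sensitivity to amplitude shifts and noise.
    """

    def __init__(self, n_coefficients: int = DEFAULT_ORDER,
                 ga_config: GAConfig | None = None, random_state: int = 0):
        self.n_coefficients = n_coefficients
        self.ga_config = ga_config
        self.random_state = random_state

    def _featurize(self, X) -> np.ndarray:
        if len(X) > 0 and isinstance(X[0], Beat):
            mat = np.stack([b.samples for b in X])
        else:
            mat = _beats_to_matrix(X)
        base = self.ga_config if self.ga_config is not None else GAConfig()
        cfg = replace(base, seed=_ga_seed(self.random_state, 1))
        return np.stack([
            model_cumulant(w, self.n_coefficients, cfg).coefficients for w in mat
        ])

    def fit(self, X, y=None):
        labels = _labels_of(X, y)
        self.bank_ = self._featurize(X)
        self.bank_labels_ = labels
        self.classes_ = np.unique(labels.astype(str))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "bank_")
        feats = self._featurize(X)
        return np.asarray(
            [nn_label(f, self.bank_, self.bank_labels_) for f in feats], dtype=object)


# -- thin functional wrappers -------------------------------------------------

def featurize(beat: Beat, n_coefficients: int = DEFAULT_ORDER,
              ga_config: GAConfig | None = None, random_state: int = 0):
    """(order-2, order-3, order-4) feature vectors for one beat."""
    est = CumulantHermite1NN(n_coefficients=n_coefficients,
                             ga_config=ga_config, random_state=random_state)
    feats = est._featurize_one(np.asarray(beat.waveform, dtype=float))
    return tuple(feats[o] for o in ORDERS)


def train(beats, **params) -> CumulantHermite1NN:
    """Fit a fused cumulant-model classifier on labelled beats."""
    return CumulantHermite1NN(**params).fit(beats)


def classify(beat: Beat, trained: CumulantHermite1NN) -> Prediction:
    """Classify one beat with a trained classifier."""
    return trained.predict_detail([beat])[0]
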