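"""End-to-end orchestration: wavelet/Tsallis features, DNA-GA search over
(q, C, sigma) against a stratified five-fold cross-validation fitness, and
final-model classification.

The fitness of a chromosome is the mean held-out accuracy over K stratified
folds: the chromosome is decoded to (q, C, sigma), the per-sub-band Tsallis
entropies are computed at that q, and an RBF-SVM with penalty C and kernel
width sigma is trained on K-1 folds and scored on the held-out fold
(feature standardization statistics come from the training folds only).
Wavelet pyramids — and the sub-band gray-level histograms derived from
them — do not depend on q, so they are computed once per image and cached;
evaluating a new chromosome only re-weights the cached histograms.

The public surface follows the scikit-learn estimator protocol:
:class:`TsallisWaveletFeaturizer` is the feature transformer and
:class:`DnagaKsvmClassifier` the full fit/predict pipeline; the
module-level functions (``cv_fitness``, ``fit_pipeline``, ``classify``)
are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import StratifiedKFold

from . import dna_ga, entropy, kernel_svm, wavelet
from .dna_ga import Chromosome, GAConfig, GenerationRecord, ParameterSpec
from .kernel_svm import KernelSVC

#: search intervals for (q, C, sigma); q in (0, 1) reflects the
#: sub-extensive prior for brain tissue, with (0, 2) as the alternative
DEFAULT_SPECS = [
    ParameterSpec("q", 1e-6, 1.0),
    ParameterSpec("C", 50.0, 200.0),
    ParameterSpec("sigma", 0.5, 2.0),
]
WIDE_Q_SPECS = [
    ParameterSpec("q", 1e-6, 2.0),
    ParameterSpec("C", 50.0, 200.0),
    ParameterSpec("sigma", 0.5, 2.0),
]


def preprocess_image(img: np.ndarray, target: int = 128) -> np.ndarray:
    """Clip to [0, +inf), rescale >1 images, resize bilinearly to a square
    dyadic side so a 3-level decomposition leaves a (target/8)^2 LL band."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    img = np.maximum(img, 0.0)
    if img.max() > 1.0:
        img = img / img.max()
    if img.shape != (target, target):
        img = resize(img, (target, target), order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    return img


class SubbandHistogramCache:
    """Per-image sub-band gray-level histograms, computed once.

    ``features(q)`` turns the cached probability array of shape
    (n_images, 3J+1, n_bins) into Tsallis-entropy features at any q without
    touching the wavelet transform again.
    """

    def __init__(self, images, levels: int = 3, n_bins: int = 256,
                 image_size: int = 128):
        self.levels = levels
        self.n_bins = n_bins
        probs = []
        for img in images:
            pyr = wavelet.dwt2d_multilevel(
                preprocess_image(img, image_size), levels
            )
            hists = entropy.subband_histograms(pyr, n_bins)
            probs.append([h.probabilities for h in hists])
        self.probabilities = np.asarray(probs)  # (n, 3J+1, n_bins)

    def __len__(self) -> int:
        return len(self.probabilities)

    def features(self, q: float) -> np.ndarray:
        if q <= 0:
            raise ValueError("q must be > 0")
        p = self.probabilities
        if abs(q - 1.0) < 1e-9:
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(p > 0, p * np.log(p), 0.0)
            return -plogp.sum(axis=-1)
        return (1.0 - np.power(p, q).sum(axis=-1)) / (q - 1.0)


class TsallisWaveletFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: images -> per-sub-band Tsallis entropies.

    Produces 3*levels + 1 features per image (10 for the default 3-level
    decomposition), ordered LL_J then (HL, LH, HH) for levels 1..J.
    """

    def __init__(self, q: float = 0.8, levels: int = 3, n_bins: int = 256,
                 image_size: int = 128):
        self.q = q
        self.levels = levels
        self.n_bins = n_bins
        self.image_size = image_size

    def fit(self, X, y=None):
        self.n_features_out_ = 3 * self.levels + 1
        return self

    def transform(self, X) -> np.ndarray:
        cache = SubbandHistogramCache(X, self.levels, self.n_bins,
                                      self.image_size)
        return cache.features(self.q)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold id per observation; per-class counts differ by at most one
    across folds, deterministic under a fixed seed."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs >= {k} members for {k}-fold stratification"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(
        skf.split(np.zeros((len(labels), 1)), labels)
    ):
        fold_of[test_idx] = fold
    return fold_of


def _fold_accuracies(features, labels, fold_of, C, sigma) -> np.ndarray:
    k = fold_of.max() + 1
    accs = np.empty(k)
    for fold in range(k):
        test = fold_of == fold
        model = KernelSVC(C=C, sigma=sigma).fit(features[~test],
                                                labels[~test])
        pred = model.predict(features[test])
        accs[fold] = np.mean(pred == labels[test])
    return accs


def cv_fitness(
    cache: SubbandHistogramCache,
    labels,
    chrom: Chromosome,
    specs: list[ParameterSpec],
    fold_of: np.ndarray,
) -> float:
    """Mean held-out accuracy over the folds at the decoded (q, C, sigma)."""
    q, C, sigma = dna_ga.decode(chrom, specs)
    features = cache.features(q)
    return float(np.mean(_fold_accuracies(features, np.asarray(labels),
                                          fold_of, C, sigma)))


@dataclass
class PipelineResult:
    best_params: tuple[float, float, float]  # (q*, C*, sigma*)
    model: KernelSVC
    cv_fitness: float
    history: list[GenerationRecord] = field(default_factory=list)
    levels: int = 3
    n_bins: int = 256
    image_size: int = 128


class DnagaKsvmClassifier(BaseEstimator, ClassifierMixin):
    """Benign/malignant image classifier with DNA-GA-tuned (q, C, sigma).

    ``fit`` takes a list/array of 2-D grayscale images with labels in
    {-1, +1} (+1 = malignant); it runs the genetic search against the
    stratified K-fold fitness and refits one RBF-SVM on all data at the
    best parameters.  ``predict`` classifies new images.

    Parameters mirror :class:`~dnaga_ksvm.dna_ga.GAConfig` plus the feature
    settings; ``random_state`` seeds three independent streams (data order
    is never touched): fold assignment, the GA, and any tie-breaking.

    Attributes (after fit)
    ----------------------
    q_, C_, sigma_ : float
        Best decoded parameters.
    cv_fitness_ : float
        Mean five-fold held-out accuracy at the best parameters.
    model_ : KernelSVC
        Final model trained on all data.
    history_ : list[GenerationRecord]
        Per-generation best/mean fitness.
    """

    def __init__(
        self,
        param_specs=None,
        population_size: int = 20,
        max_generations: int = 30,
        crossover_prob: float = 0.8,
        mutation_prob: float = 0.02,
        fitness_tolerance: float = 1e-4,
        stall_generations: int = 3,
        levels: int = 3,
        n_bins: int = 256,
        image_size: int = 128,
        k_folds: int = 5,
        random_state: int = 0,
    ):
        self.param_specs = param_specs
        self.population_size = population_size
        self.max_generations = max_generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.fitness_tolerance = fitness_tolerance
        self.stall_generations = stall_generations
        self.levels = levels
        self.n_bins = n_bins
        self.image_size = image_size
        self.k_folds = k_folds
        self.random_state = random_state

    def _specs(self) -> list[ParameterSpec]:
        return list(self.param_specs) if self.param_specs else DEFAULT_SPECS

    def fit(self, X, y):
        labels = np.asarray(y)
        if len(X) != len(labels):
            raise ValueError("one label per image is required")
        specs = self._specs()
        seeds = np.random.SeedSequence(self.random_state).generate_state(2)
        fold_seed, ga_seed = (int(s % 2**31) for s in seeds)
        cache = SubbandHistogramCache(X, self.levels, self.n_bins,
                                      self.image_size)
        fold_of = stratified_kfold(labels, self.k_folds, seed=fold_seed)
        config = GAConfig(
            population_size=self.population_size,
            max_generations=self.max_generations,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            fitness_tolerance=self.fitness_tolerance,
            stall_generations=self.stall_generations,
            seed=ga_seed,
        )
        best, (q, C, sigma), history = dna_ga.evolve(
            lambda c: cv_fitness(cache, labels, c, specs, fold_of),
            specs,
            config,
        )
        self.q_, self.C_, self.sigma_ = q, C, sigma
        self.cv_fitness_ = best.fitness
        self.history_ = history
        self.fold_of_ = fold_of
        self._cache = cache
        self.classes_ = np.array([kernel_svm.NEGATIVE, kernel_svm.POSITIVE])
        self.model_ = KernelSVC(C=C, sigma=sigma).fit(cache.features(q),
                                                      labels)
        return self

    def _features(self, X) -> np.ndarray:
        cache = SubbandHistogramCache(X, self.levels, self.n_bins,
                                      self.image_size)
        return cache.features(self.q_)

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(self._features(X))

    def decision_function(self, X) -> np.ndarray:
        return self.model_.decision_function(self._features(X))

    def cv_confusion(self, y) -> kernel_svm.ConfusionMatrix:
        """Held-out confusion counts at the tuned parameters: each fold is
        predicted by a model trained on the other folds."""
        labels = np.asarray(y)
        feats = self._cache.features(self.q_)
        pred = np.empty(len(labels), dtype=int)
        for fold in range(self.k_folds):
            test = self.fold_of_ == fold
            m = KernelSVC(C=self.C_, sigma=self.sigma_).fit(
                feats[~test], labels[~test]
            )
            pred[test] = m.predict(feats[test])
        return kernel_svm.confusion_and_metrics(labels, pred)

    def result(self) -> PipelineResult:
        return PipelineResult(
            best_params=(self.q_, self.C_, self.sigma_),
            model=self.model_,
            cv_fitness=self.cv_fitness_,
            history=self.history_,
            levels=self.levels,
            n_bins=self.n_bins,
            image_size=self.image_size,
        )


def fit_pipeline(images, labels, specs=None,
                 ga_config: GAConfig | None = None) -> PipelineResult:
    """Functional wrapper over :class:`DnagaKsvmClassifier`."""
    config = ga_config or GAConfig()
    clf = DnagaKsvmClassifier(
        param_specs=specs,
        population_size=config.population_size,
        max_generations=config.max_generations,
        crossover_prob=config.crossover_prob,
        mutation_prob=config.mutation_prob,
        fitness_tolerance=config.fitness_tolerance,
        stall_generations=config.stall_generations,
        random_state=config.seed,
    )
    clf.fit(images, labels)
    return clf.result()


def classify(result: PipelineResult, image: np.ndarray) -> int:
    """Label one image with a fitted pipeline: -1 benign, +1 malignant."""
    q = result.best_params[0]
    img = preprocess_image(image, result.image_size)
    pyr = wavelet.dwt2d_multilevel(img, result.levels)
    feats = entropy.extract_features(pyr, q, result.n_bins).values
    return int(result.model.predict(feats[None, :])[0])
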