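"""Image-level prediction from subwindow ensembles.

Two modes mirror the two ways a trained forest is exploited:

* **C mode** — every subwindow is propagated through every tree; the leaf
  class-frequency vectors are averaged over all (subwindow, tree) pairs and
  the image takes the most probable class.
* **BAGS mode** — the image is summarized by how often its subwindows land
  in each leaf of each tree (a bag-of-visual-words over the ensemble's leaf
  vocabulary, normalized per tree), and a linear SVM classifies that
  descriptor.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import LinearSVC

from zfscreen.ert import Ensemble, propagate_many
from zfscreen.subwindow import SamplerParams, image_features


class ModelError(RuntimeError):
    """Raised when a model is untrained or pieces do not fit together."""


def _check_trained(ensemble: Ensemble) -> None:
    if not ensemble.trees or ensemble.n_leaves == 0:
        raise ModelError("ensemble is untrained")


def predict_C_vectors(vectors: np.ndarray, ensemble: Ensemble) -> np.ndarray:
    """Mean leaf class-frequency vector over all (subwindow, tree) pairs."""
    _check_trained(ensemble)
    vectors = np.atleast_2d(vectors)
    dists = ensemble.leaf_distributions()
    acc = np.zeros(ensemble.n_classes)
    for tree in ensemble.trees:
        leaves = propagate_many(vectors, tree)
        acc += dists[leaves].sum(axis=0)
    proba = acc / (vectors.shape[0] * len(ensemble.trees))
    return proba


def predict_C(
    img: np.ndarray,
    ensemble: Ensemble,
    sampler: SamplerParams,
    image_id: int | str = 0,
) -> tuple[np.ndarray, str]:
    """Direct-vote prediction: (class probabilities, label).

    Subwindows are sampled with the same parameters used for training; ties
    in the argmax go to the first class in the model's class order.
    """
    vectors = image_features(img, sampler, image_id=image_id)
    proba = predict_C_vectors(vectors, ensemble)
    label = ensemble.class_names[int(np.argmax(proba))]
    return proba, label


def bags_descriptor_vectors(
    vectors: np.ndarray, ensemble: Ensemble, normalize: bool = True
) -> np.ndarray:
    """Leaf-frequency descriptor of a set of patch vectors.

    Arrival counts per leaf, normalized per tree by the number of
    subwindows, so every per-tree block sums to 1 and descriptors are
    comparable across images; ``normalize=False`` keeps raw counts.
    """
    _check_trained(ensemble)
    vectors = np.atleast_2d(vectors)
    desc = np.zeros(ensemble.n_leaves)
    for tree in ensemble.trees:
        leaves = propagate_many(vectors, tree)
        desc += np.bincount(leaves, minlength=ensemble.n_leaves)
    return desc / vectors.shape[0] if normalize else desc


def bags_descriptor(
    img: np.ndarray,
    ensemble: Ensemble,
    sampler: SamplerParams,
    image_id: int | str = 0,
    normalize: bool = True,
) -> np.ndarray:
    """BAGS descriptor of an image (length = total leaf count)."""
    vectors = image_features(img, sampler, image_id=image_id)
    return bags_descriptor_vectors(vectors, ensemble, normalize=normalize)


def train_bags_svm(descriptors: np.ndarray, labels: list[str] | np.ndarray) -> LinearSVC:
    """Fit the linear one-vs-rest maximum-margin classifier on descriptors.

    C = 1.0 with squared-hinge loss; the primal solver makes the fit
    deterministic. Raises on single-class input.
    """
    X = np.atleast_2d(np.asarray(descriptors))
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to train an SVM")
    svm = LinearSVC(C=1.0, loss="squared_hinge", dual=False)
    svm.fit(X, y)
    return svm


def predict_BAGS(
    img: np.ndarray,
    ensemble: Ensemble,
    svm: LinearSVC,
    sampler: SamplerParams,
    image_id: int | str = 0,
) -> str:
    """BAGS prediction: descriptor then SVM decision."""
    desc = bags_descriptor(img, ensemble, sampler, image_id=image_id)
    return predict_BAGS_descriptor(desc, svm)


def predict_BAGS_descriptor(desc: np.ndarray, svm: LinearSVC) -> str:
    desc = np.atleast_2d(desc)
    if desc.shape[1] != svm.coef_.shape[1]:
        raise ModelError(
            f"descriptor length {desc.shape[1]} does not match SVM input "
            f"dimension {svm.coef_.shape[1]} (mismatched ensemble/SVM pair?)"
        )
    return str(svm.predict(desc)[0])
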