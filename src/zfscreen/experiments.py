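"""End-to-end study drivers on synthetic data.

These functions wire the generator, preprocessing, training and evaluation
together the way a screening study runs them: render labeled larvae, crop,
train the two-tier classifier on a learning set, and score an independent
test set; or simulate a dose-response plate and recover LC50/EC50/TI.
They are what the worked examples and the reproduction script execute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from zfscreen import pipeline, preprocess, synthgen
from zfscreen.subwindow import SamplerParams


@dataclass
class TwoTierResult:
    """Evaluation of a trained two-tier classifier on an independent test set."""

    model: pipeline.TwoTierModel
    gate_accuracy: float
    confusions: dict[str, pipeline.DefectConfusion]
    gate_preds: list[str]
    binary_preds: list[dict[str, bool] | None]
    truths: list[frozenset[str]]

    @property
    def confusion_frame(self) -> pd.DataFrame:
        return pipeline.confusion_table(self.confusions)


def evaluate_two_tier(
    model: pipeline.TwoTierModel,
    features: list[np.ndarray],
    truths: list[frozenset[str]],
) -> TwoTierResult:
    """Score a two-tier model on precomputed test feature clouds."""
    gate_preds: list[str] = []
    bin_preds: list[dict[str, bool] | None] = []
    for f in features:
        g = model.gate.predict_vectors(f)
        gate_preds.append(g)
        if g in pipeline.EXCLUSIVE_TERMS:
            bin_preds.append(None)
        else:
            bin_preds.append(
                {d: model.binary[d].predict_vectors(f) == d for d in pipeline.NON_GATE_TERMS}
            )
    gate_truth = [pipeline.gate_class(t) for t in truths]
    gate_acc = float(np.mean([p == t for p, t in zip(gate_preds, gate_truth)]))
    conf = pipeline.aggregate_two_tier_confusion(gate_preds, bin_preds, truths)
    return TwoTierResult(model, gate_acc, conf, gate_preds, bin_preds, truths)


def run_two_tier_experiment(
    n_train: int = 40,
    n_test: int = 20,
    n_subwindows: int = 100,
    mode: str = "BAGS",
    seed: int = 0,
    canvas: int = 256,
) -> TwoTierResult:
    """Full synthetic study: generate, crop, train and evaluate.

    The learning and test sets come from disjoint generator streams and are
    tagged as separate acquisition sessions, mirroring the real protocol of
    fitting on some sessions and scoring on held-out ones.
    """
    imgs_tr, fr_tr = synthgen.generate_classification_set(
        n_train, seed=seed * 2 + 1, split="LS", session=1, canvas=canvas
    )
    imgs_te, fr_te = synthgen.generate_classification_set(
        n_test, seed=seed * 2 + 2, split="TS", session=2, canvas=canvas
    )
    crops_tr = [preprocess.locate_and_crop(im) for im in imgs_tr]
    crops_te = [preprocess.locate_and_crop(im) for im in imgs_te]
    sampler = SamplerParams(n_subwindows=n_subwindows, seed=seed)
    feat_tr = pipeline.dataset_features(crops_tr, sampler)
    feat_te = pipeline.dataset_features(crops_te, sampler)
    model = pipeline.train_two_tier(feat_tr, list(fr_tr["labels"]), sampler, mode=mode, seed=seed)
    return evaluate_two_tier(model, feat_te, list(fr_te["labels"]))


def run_dose_response_recovery(
    n_seeds: int = 100,
    spec: synthgen.PlateSpec | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Repeatedly simulate a plate and refit its curves.

    Returns one row per replicate with the fitted log10 LC50/EC50, their
    standard errors and whether each estimate fell within 3 SE of the
    generating truth.
    """
    template = spec or synthgen.PlateSpec()
    rows = []
    for i in range(n_seeds):
        sp = synthgen.PlateSpec(
            compound=template.compound,
            concentrations=template.concentrations,
            n_per_conc=template.n_per_conc,
            log_lc50=template.log_lc50,
            log_ec50=template.log_ec50,
            hill_surv=template.hill_surv,
            hill_terat=template.hill_terat,
            seed=(base_seed + i) & 0x7FFFFFFF,
        )
        _, frame = synthgen.generate_plate(sp)
        fit = pipeline.dose_response(frame)
        s, t = fit.survival, fit.teratogenicity
        rows.append(
            {
                "seed": sp.seed,
                "log_lc50": s.log_x50,
                "se_log_lc50": s.se_log_x50,
                "log_ec50": t.log_x50,
                "se_log_ec50": t.se_log_x50,
                "log_ti": fit.log_ti,
                "converged": s.converged and t.converged,
                "lc50_within_3se": bool(
                    s.converged and abs(s.log_x50 - sp.log_lc50) <= 3 * s.se_log_x50
                ),
                "ec50_within_3se": bool(
                    t.converged and abs(t.log_x50 - sp.log_ec50) <= 3 * t.se_log_x50
                ),
            }
        )
    return pd.DataFrame(rows)
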