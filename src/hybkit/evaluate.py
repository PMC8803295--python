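"""Scoring genotypic-class assignment against simulation truth.

An individual is *correctly assigned* at a threshold t when the posterior
probability of its true class is at least t (threshold semantics; an
argmax-based alternative is available behind ``criterion="argmax"``).
It is *misassigned* when some other class is called at the threshold, and
*unassigned* otherwise; the three proportions sum to one per true class.

Because several classes share identical ancestry profiles under the
per-locus-independent model ({B1,B3}, {B5,B7}, {B6,B8}, {F2,F3,F4}),
``equivalence_aware=True`` merges each confounded group (summing posterior
columns and relabelling truth) before scoring — the resolution limit the
strict scores run into is then removed from the bookkeeping.

``replicate_assignment_study`` runs the full three-arm evaluation design:
six-class data scored with the six-class model, fourteen-class data with
the six-class model, and fourteen-class data with the twelve-class model,
over replicate simulated datasets, and aggregates per-class correct
proportions (both averaged over datasets and pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassPosteriorMatrix, McmcConfig, classify, purity_call
from .geno_io import AlleleFreqTable, GenotypeTable
from .pedigrees import CONFOUNDED_GROUPS, class_profiles
from .simulate import SimConfig, build_evaluation_datasets

DEFAULT_THRESHOLDS = (0.5, 0.75, 0.85, 0.9)


@dataclass
class EvaluationReport:
    """Per-(true class, threshold) outcome proportions and confusions."""

    per_class: pd.DataFrame        # true_class, threshold, correct, ...
    confusion: dict[float, pd.DataFrame] = field(default_factory=dict)
    parental_average: dict[float, float] = field(default_factory=dict)

    def to_tsv(self) -> str:
        return self.per_class.to_csv(sep="\t", index=False)


def _merge_confounded(post: ClassPosteriorMatrix, truth: dict[str, str],
                      ) -> tuple[ClassPosteriorMatrix, dict[str, str]]:
    rep = {}
    for group in CONFOUNDED_GROUPS:
        members = sorted(group)
        label = "/".join(members)
        for m in members:
            rep[m] = label
    new_names: list[str] = []
    for name in post.class_names:
        merged = rep.get(name, name)
        if merged not in new_names:
            new_names.append(merged)
    probs = np.zeros((post.probs.shape[0], len(new_names)))
    for k, name in enumerate(post.class_names):
        probs[:, new_names.index(rep.get(name, name))] += post.probs[:, k]
    merged_post = ClassPosteriorMatrix(list(post.individual_ids), new_names,
                                       probs, dict(post.diagnostics))
    merged_truth = {i: rep.get(c, c) for i, c in truth.items()}
    return merged_post, merged_truth


def evaluate_assignments(post: ClassPosteriorMatrix, truth: dict[str, str],
                         thresholds=DEFAULT_THRESHOLDS,
                         equivalence_aware: bool = False,
                         criterion: str = "posterior") -> EvaluationReport:
    """Score a posterior matrix against true class labels.

    ``truth`` must cover every individual in ``post``; true classes absent
    from the model's class set are legitimate (their correct proportion is
    necessarily zero) — this is the 14-classes-on-6-model situation.
    """
    if criterion not in ("posterior", "argmax"):
        raise ValueError("criterion must be 'posterior' or 'argmax'")
    missing = [i for i in post.individual_ids if i not in truth]
    if missing:
        raise ValueError(f"truth labels missing for: {missing[:10]}")
    if equivalence_aware:
        post, truth = _merge_confounded(post, truth)

    name_idx = {c: k for k, c in enumerate(post.class_names)}
    true_classes = list(dict.fromkeys(truth[i] for i in post.individual_ids))
    rows = []
    confusion: dict[float, pd.DataFrame] = {}
    parental: dict[float, float] = {}
    for t in thresholds:
        if not 0.0 < t <= 1.0:
            raise ValueError("thresholds must lie in (0, 1]")
        calls = purity_call(post, t)
        conf = pd.DataFrame(
            0, index=true_classes,
            columns=list(post.class_names) + ["unassigned"])
        for i, ind in enumerate(post.individual_ids):
            conf.loc[truth[ind], calls[ind]] += 1
        confusion[t] = conf
        for cls in true_classes:
            mask = np.asarray([truth[i] == cls for i in post.individual_ids])
            n_cls = int(mask.sum())
            if criterion == "posterior":
                k = name_idx.get(cls)
                correct = float(np.mean(post.probs[mask, k] >= t)) \
                    if k is not None else 0.0
            else:
                correct = float(conf.loc[cls, cls] / n_cls) \
                    if cls in name_idx else 0.0
            unassigned = float(conf.loc[cls, "unassigned"] / n_cls)
            mis = max(0.0, 1.0 - correct - unassigned)
            rows.append({"true_class": cls, "threshold": t,
                         "correct": correct, "misassigned": mis,
                         "unassigned": unassigned, "n": n_cls})
        pure = [c for c in ("P1", "P2") if c in true_classes]
        if pure:
            vals = [r["correct"] for r in rows
                    if r["threshold"] == t and r["true_class"] in pure]
            parental[t] = float(np.mean(vals))
    return EvaluationReport(pd.DataFrame(rows), confusion, parental)


def aggregate_reports(reports: list[EvaluationReport],
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(mean-over-datasets, pooled) per-class correct proportions.

    With equal per-class n in every dataset the two coincide; both are
    returned since the choice is a reporting convention.
    """
    stacked = pd.concat([r.per_class for r in reports], ignore_index=True)
    mean = (stacked.groupby(["true_class", "threshold"], sort=False)
            [["correct", "misassigned", "unassigned"]].mean().reset_index())
    pooled = (stacked
              .assign(cw=stacked["correct"] * stacked["n"],
                      mw=stacked["misassigned"] * stacked["n"],
                      uw=stacked["unassigned"] * stacked["n"])
              .groupby(["true_class", "threshold"], sort=False)
              .apply(lambda g: pd.Series({
                  "correct": g["cw"].sum() / g["n"].sum(),
                  "misassigned": g["mw"].sum() / g["n"].sum(),
                  "unassigned": g["uw"].sum() / g["n"].sum()}),
                  include_groups=False)
              .reset_index())
    return mean, pooled


ARMS = ("6on6", "14on6", "14on12")


def replicate_assignment_study(pools: tuple[AlleleFreqTable, AlleleFreqTable],
                               sim_cfg: SimConfig, mcmc_cfg: McmcConfig,
                               arms=ARMS, thresholds=DEFAULT_THRESHOLDS,
                               equivalence_aware: bool = False,
                               ) -> dict[str, tuple[pd.DataFrame,
                                                    pd.DataFrame]]:
    """Run the three-arm simulation evaluation of the class posterior.

    Arm ``XonY`` simulates the X-class set and classifies with the Y-class
    model.  Returns per arm the (mean, pooled) aggregated reports.
    """
    results: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    datasets: dict[str, list[GenotypeTable]] = {}
    for arm in arms:
        sim_set = {"6on6": "six", "14on6": "fourteen",
                   "14on12": "fourteen"}[arm]
        model_set = {"6on6": "six", "14on6": "six", "14on12": "twelve"}[arm]
        if sim_set not in datasets:
            cfg = SimConfig(**{**sim_cfg.__dict__, "class_set": sim_set})
            datasets[sim_set] = build_evaluation_datasets(pools, cfg)
        classes = class_profiles(model_set)
        reports = []
        for d, gt in enumerate(datasets[sim_set]):
            cfg_d = McmcConfig(**{**mcmc_cfg.__dict__,
                                  "seed": mcmc_cfg.seed + 1000 * d})
            post = classify(gt, classes, cfg_d)
            truth = {ind: str(pop) for ind, pop in
                     zip(gt.individual_ids, gt.populations)}
            reports.append(evaluate_assignments(
                post, truth, thresholds,
                equivalence_aware=equivalence_aware))
        results[arm] = aggregate_reports(reports)
    return results
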