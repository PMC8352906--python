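"""End-to-end orchestration: split, fit all families, classify queries,
tabulate a report, and build distance dendrograms.

``run_all`` fits the six classifier families on both representations (raw
counts and relative percentages), reports held-out accuracy per family ×
representation, and classifies query assemblages against models refitted on
the full reference set.  A family that fails to converge on one cell is
marked ``"N.C."`` and the run continues.  ``dendrogram`` reproduces the
distance-clustering view: agglomerative average-linkage clustering of the
series, cut into a fixed number of flat groups, serialised as Newick.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .series import AssemblageSeries, LabeledDataset, CLASS_ORDER
from .classifiers import (
    BossClassifier,
    BossVsClassifier,
    ClassifierVerdict,
    KnnDtwClassifier,
    MtfClassifier,
    SaxVsmClassifier,
    WeaselClassifier,
)
from . import ensemble as ens

NOT_CONVERGED = "N.C."


def split(
    dataset: LabeledDataset, test_fraction: float = 0.25, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified, seeded train/test split."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    y = dataset.y
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        if len(idx) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


def default_classifiers(
    series_length: int, mode: str, seed: int = 0
) -> dict[str, Callable[[], object]]:
    """Factories for the six families at their reference configurations.

    The WEASEL window sweep tops out at 110 for raw series and 80 for
    relative series; the BOSS window spans all but one point of the series.
    """
    weasel_hi = min(110 if mode == "raw" else 80, series_length - 1)
    boss_window = min(119, series_length - 1)
    return {
        "knn_dtw": lambda: KnnDtwClassifier(k=1),
        "boss_vs": lambda: BossVsClassifier(word_sizes=(2, 3, 4), alphabet=2),
        "sax_vsm": lambda: SaxVsmClassifier(
            word_size=6, n_bins_symbols=2, strategy="normal",
            window_size=min(30, series_length),
        ),
        "boss": lambda: BossClassifier(
            word_size=4, window_size=boss_window, alphabet=2, backend="knn"
        ),
        "weasel": lambda: WeaselClassifier(
            word_size=4, window_range=(5, weasel_hi), alphabet=4
        ),
        "mtf": lambda: MtfClassifier(
            backend="random_forest", image_size=0.1, n_bins=6, seed=seed
        ),
    }


@dataclass
class RunReport:
    """Tabulated outcome of a full pipeline run."""

    accuracies: dict[tuple[str, str], float | str]
    verdicts: dict[tuple[str, str, str], ClassifierVerdict]
    ensemble_metrics: dict[str, dict]
    ensemble_verdicts: dict[tuple[str, str], ClassifierVerdict]

    def accuracy_table(self) -> pd.DataFrame:
        """Family × representation accuracy grid (reference-table layout)."""
        algos = sorted({a for a, _ in self.accuracies})
        return pd.DataFrame(
            {
                mode: [self.accuracies.get((a, mode), np.nan) for a in algos]
                for mode in ("raw", "relative")
            },
            index=algos,
        )

    def verdict_table(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": sid,
                "algorithm": algo,
                "mode": mode,
                "label": v.predicted,
                "probability": v.probability,
            }
            for (algo, mode, sid), v in self.verdicts.items()
        ]
        return pd.DataFrame(rows)


def run_all(
    train: LabeledDataset,
    test: LabeledDataset,
    queries: Sequence[AssemblageSeries] = (),
    seed: int = 0,
    with_ensembles: bool = True,
    classifier_factories: Mapping[str, Mapping[str, Callable]] | None = None,
) -> RunReport:
    """Fit every family on raw and relative series; classify the queries.

    Queries are classified by models refitted on the full reference set
    (train + test) after evaluation: held-out accuracy validates the
    framework, but archaeological assemblages are compared against all the
    experimental evidence available.
    """
    accuracies: dict[tuple[str, str], float | str] = {}
    verdicts: dict[tuple[str, str, str], ClassifierVerdict] = {}
    L = train.X.shape[1]
    datasets = {"raw": (train, test)}
    rel_ok = all(s.values.sum() > 0 for s in train.series + test.series)
    if rel_ok:
        datasets["relative"] = (train.to_relative(), test.to_relative())
    full = LabeledDataset(
        train.series + test.series, train.labels + test.labels
    )
    for mode, (tr, te) in datasets.items():
        factories = (
            classifier_factories[mode]
            if classifier_factories is not None
            else default_classifiers(L, mode, seed)
        )
        full_mode = full if mode == "raw" else full.to_relative()
        for name, factory in factories.items():
            try:
                clf = factory().fit(tr.X, tr.y)
                acc = float(np.mean(clf.predict(te.X) == te.y))
                accuracies[(name, mode)] = acc
            except Exception:
                accuracies[(name, mode)] = NOT_CONVERGED
                continue
            if queries:
                try:
                    qclf = factory().fit(full_mode.X, full_mode.y)
                    for q in queries:
                        qv = q.values
                        if mode == "relative" and q.mode == "raw":
                            qv = 100.0 * qv / qv.sum()
                        verdicts[(name, mode, q.sample_id)] = qclf.classify(qv)
                except Exception:
                    for q in queries:
                        verdicts[(name, mode, q.sample_id)] = ClassifierVerdict(
                            name, NOT_CONVERGED
                        )
    ensemble_metrics: dict[str, dict] = {}
    ensemble_verdicts: dict[tuple[str, str], ClassifierVerdict] = {}
    if with_ensembles and rel_ok:
        tr_rel, te_rel = datasets["relative"]
        cfg = ens.EnsembleConfig(seed=seed)
        model = ens.fit_stacked(tr_rel, cfg)
        ensemble_metrics["stacked"] = ens.evaluate(
            lambda x: ens.predict_stacked(model, x), te_rel
        )
        ensemble_metrics["majority"] = ens.evaluate(
            lambda x: ens.majority_vote(model.bases, x), te_rel
        )
        ensemble_metrics["base_learners"] = model.base_metrics
        full_rel = full.to_relative()
        qmodel = ens.fit_stacked(full_rel, cfg)
        for q in queries:
            qv = q.values
            if q.mode == "raw":
                qv = 100.0 * qv / qv.sum()
            ensemble_verdicts[("stacked", q.sample_id)] = ens.predict_stacked(
                qmodel, qv
            )
            ensemble_verdicts[("majority", q.sample_id)] = ens.majority_vote(
                qmodel.bases, qv
            )
    return RunReport(accuracies, verdicts, ensemble_metrics, ensemble_verdicts)


def dendrogram(
    samples: Sequence[AssemblageSeries],
    n_groups: int = 25,
    metric: str = "euclidean",
) -> tuple[np.ndarray, dict[str, int], str]:
    """Average-linkage clustering of assemblage series.

    Returns the linkage matrix, a sample_id → flat-group assignment (the
    tree cut into ``n_groups`` groups, reduced with a warning if there are
    fewer samples), and the tree serialised as a Newick string with sample
    ids as leaf names.
    """
    import warnings

    if len(samples) < 2:
        raise ValueError("clustering needs at least 2 samples")
    X = np.stack([s.values for s in samples])
    ids = [s.sample_id for s in samples]
    if n_groups > len(samples):
        warnings.warn(
            f"n_groups={n_groups} exceeds {len(samples)} samples; reduced",
            stacklevel=2,
        )
        n_groups = len(samples)
    Z = linkage(pdist(X, metric=metric), method="average")
    flat = fcluster(Z, t=n_groups, criterion="maxclust")
    groups = {sid: int(g) for sid, g in zip(ids, flat)}
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, ids)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return Z, groups, buf.getvalue().strip()
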