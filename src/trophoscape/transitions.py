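"""Observed-vs-predicted structure comparison and human-impact attribution.

Disagreements between the structure a cell actually carries and the one its
climate predicts are typed: type I — observed depauperate where boreal or
temperate is predicted; type II — observed semi-arid where seasonal or humid
tropical is predicted; island — island cells, which are depauperate
regardless of climate.  Agreement is quantified with Cohen's kappa, and the
relationship of transitions to human-impact indicators is tested with
Student's t tests and modelled with evolutionary impact trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix

from trophoscape.climate_tree import EvolutionConfig, TreeModel, evolve_tree
from trophoscape.structures import ImpactTable, StructureClassification

__all__ = [
    "TransitionMap",
    "AgreementReport",
    "ImpactComparison",
    "compare_structures",
    "kappa_agreement",
    "impact_ttests",
    "impact_tree",
    "COLD_LABELS",
    "TROPICAL_LABELS",
]

COLD_LABELS = ("boreal", "temperate")
TROPICAL_LABELS = ("seasonal_tropical", "humid_tropical")
DISAGREEMENT_TYPES = ("none", "typeI", "typeII", "island", "other")


@dataclass
class TransitionMap:
    """Per-cell observed and climate-predicted labels with disagreement type."""

    table: pd.DataFrame  # columns: cell_id, observed, predicted, type

    def counts(self) -> dict[str, int]:
        c = self.table["type"].value_counts().to_dict()
        return {t: int(c.get(t, 0)) for t in DISAGREEMENT_TYPES}

    def cells_of_type(self, dtype: str) -> list[str]:
        return self.table.loc[self.table["type"] == dtype, "cell_id"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class AgreementReport:
    """Cohen's kappa with its ingredients: kappa = (p_o - p_e) / (1 - p_e)."""

    confusion: pd.DataFrame
    p_observed: float
    p_chance: float
    kappa: float

    def to_dict(self) -> dict:
        return {
            "p_observed": self.p_observed,
            "p_chance": self.p_chance,
            "kappa": self.kappa,
            "n": int(self.confusion.to_numpy().sum()),
        }


@dataclass
class ImpactComparison:
    """Per-indicator changed-vs-unchanged group comparison (Student's t)."""

    table: pd.DataFrame  # indicator, mean_changed, mean_unchanged, t, p, n_changed, n_unchanged
    welch: bool = False


def compare_structures(
    observed: StructureClassification | pd.Series | np.ndarray,
    predicted: np.ndarray,
    island: np.ndarray | None = None,
    cell_ids: list[str] | None = None,
) -> TransitionMap:
    """Type every cell's observed/predicted disagreement.

    The island flag overrides: island cells are typed ``island`` whatever
    their labels.  Mainland cells agree (``none``), are ``typeI`` (observed
    depauperate, predicted boreal/temperate), ``typeII`` (observed semi-arid,
    predicted seasonal/humid tropical), or ``other``.
    """
    if isinstance(observed, StructureClassification):
        cell_ids = list(observed.cell_ids)
        obs = np.asarray(observed.labels, dtype=object)
    else:
        obs = np.asarray(observed, dtype=object)
        if cell_ids is None:
            cell_ids = [f"c{i}" for i in range(len(obs))]
    pred = np.asarray(predicted, dtype=object)
    if len(obs) != len(pred):
        raise ValueError("observed and predicted differ in length")
    vocab_obs, vocab_pred = set(map(str, obs)), set(map(str, pred))
    if vocab_obs.isdisjoint(vocab_pred):
        raise ValueError(
            f"label vocabulary mismatch: observed {sorted(vocab_obs)} vs predicted {sorted(vocab_pred)}"
        )
    island = np.zeros(len(obs), dtype=bool) if island is None else np.asarray(island, dtype=bool)

    dtype = np.full(len(obs), "other", dtype=object)
    dtype[obs == pred] = "none"
    type1 = (obs == "depauperate") & np.isin(pred.astype(str), COLD_LABELS)
    type2 = (obs == "semiarid") & np.isin(pred.astype(str), TROPICAL_LABELS)
    dtype[type1] = "typeI"
    dtype[type2] = "typeII"
    dtype[island] = "island"
    return TransitionMap(
        pd.DataFrame(
            {"cell_id": cell_ids, "observed": obs.astype(str), "predicted": pred.astype(str), "type": dtype.astype(str)}
        )
    )


def kappa_agreement(labels_a, labels_b) -> AgreementReport:
    """Cohen's kappa between two labelings of the same cells.

    Chance agreement uses the product of the two marginal distributions.
    """
    a = np.asarray(labels_a, dtype=str)
    b = np.asarray(labels_b, dtype=str)
    if len(a) == 0:
        raise ValueError("empty label vectors")
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    vocab = sorted(set(a) | set(b))
    cm = confusion_matrix(a, b, labels=vocab)
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    return AgreementReport(
        confusion=pd.DataFrame(cm, index=vocab, columns=vocab),
        p_observed=float(p_o),
        p_chance=p_e,
        kappa=float(kappa),
    )


def _changed_unchanged_cells(
    tmap: TransitionMap, disagreement_type: str
) -> tuple[list[str], list[str]]:
    """Changed cells of the given type vs unchanged cells of the matching
    climatic super-group (cold for type I, warm-tropical for type II)."""
    t = tmap.table
    changed = t.loc[t["type"] == disagreement_type, "cell_id"].tolist()
    if disagreement_type == "typeI":
        group = COLD_LABELS
    elif disagreement_type == "typeII":
        group = TROPICAL_LABELS
    else:
        raise ValueError("disagreement_type must be 'typeI' or 'typeII'")
    unchanged = t.loc[
        (t["type"] == "none") & t["predicted"].isin(group), "cell_id"
    ].tolist()
    return changed, unchanged


def impact_ttests(
    tmap: TransitionMap,
    impacts: ImpactTable,
    disagreement_type: str = "typeI",
    welch: bool = False,
) -> ImpactComparison:
    """Student's t test per impact indicator, changed vs unchanged cells.

    Classical equal-variance t by default; ``welch=True`` drops the
    equal-variance assumption.  p values are two-sided and uncorrected
    across indicators.
    """
    changed, unchanged = _changed_unchanged_cells(tmap, disagreement_type)
    if len(changed) < 2 or len(unchanged) < 2:
        raise ValueError(
            f"both groups need >= 2 cells (changed={len(changed)}, unchanged={len(unchanged)})"
        )
    tc = impacts.for_cells(changed)
    tu = impacts.for_cells(unchanged)
    rows = []
    for col in ImpactTable.REQUIRED:
        res = stats.ttest_ind(tc[col], tu[col], equal_var=not welch)
        rows.append(
            {
                "indicator": col,
                "mean_changed": float(tc[col].mean()),
                "mean_unchanged": float(tu[col].mean()),
                "t": float(res.statistic),
                "p": float(res.pvalue),
                "n_changed": len(tc),
                "n_unchanged": len(tu),
            }
        )
    return ImpactComparison(pd.DataFrame(rows), welch=welch)


def impact_tree(
    tmap: TransitionMap,
    impacts: ImpactTable,
    disagreement_type: str = "typeI",
    config: EvolutionConfig | None = None,
) -> TreeModel:
    """Evolve a changed-vs-unchanged tree over the six impact indicators.

    With no changed cells the model is the trivial single-leaf "unchanged".
    """
    changed, unchanged = _changed_unchanged_cells(tmap, disagreement_type)
    cells = changed + unchanged
    y = np.array(["changed"] * len(changed) + ["unchanged"] * len(unchanged))
    X = impacts.for_cells(cells)[ImpactTable.REQUIRED]
    return evolve_tree(X, y, config)
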