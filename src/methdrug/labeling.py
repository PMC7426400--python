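"""AUCDR trichotomization and pair-feature construction.

Drug responses are categorized rather than regressed: AUCDR < 0.2 is
sensitive, AUCDR > 0.991 is resistant (both strictly), everything in
between is unclear and excluded from training. The labeled (cell, drug)
records form the edge list of a bipartite cell-drug graph; each trainable
edge is featurized by vector-space integration (VSI): the cell's row of
the cell-similarity matrix concatenated with the drug's row of the
drug-similarity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ResponseTable, ValidationError
from .similarity import SimilarityMatrix

log = logging.getLogger(__name__)

SENSITIVE = "sensitive"
RESISTANT = "resistant"
UNCLEAR = "unclear"

T_SENS = 0.2
T_RES = 0.991

__all__ = [
    "SENSITIVE",
    "RESISTANT",
    "UNCLEAR",
    "T_SENS",
    "T_RES",
    "LabeledPairSet",
    "PairFeatures",
    "label_response",
    "build_pair_set",
    "vsi_features",
    "cross_vsi_features",
]


def label_response(aucdr: float, t_sens: float = T_SENS, t_res: float = T_RES) -> str:
    """Strict-threshold trichotomization of one AUCDR value.

    Values equal to a threshold are unclear (the rule is strictly
    "less than" / "larger than").
    """
    if not (0.0 <= aucdr <= 1.0):
        raise ValidationError(f"AUCDR {aucdr!r} outside [0,1]")
    if aucdr < t_sens:
        return SENSITIVE
    if aucdr > t_res:
        return RESISTANT
    return UNCLEAR


@dataclass
class LabeledPairSet:
    """(cell, drug, aucdr, label) records plus the thresholds that made them."""

    records: pd.DataFrame  # columns: cell_id, drug_id, aucdr, label
    t_sens: float = T_SENS
    t_res: float = T_RES

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.records["label"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in (SENSITIVE, RESISTANT, UNCLEAR)}

    def trainable(self) -> pd.DataFrame:
        """Records with a definite label (unclear pairs are flagged out)."""
        return self.records[self.records["label"] != UNCLEAR].reset_index(drop=True)


def build_pair_set(responses: ResponseTable, t_sens: float = T_SENS, t_res: float = T_RES) -> LabeledPairSet:
    df = responses.records.copy()
    a = df["aucdr"].to_numpy()
    df["label"] = np.select([a < t_sens, a > t_res], [SENSITIVE, RESISTANT], default=UNCLEAR)
    out = LabeledPairSet(df, t_sens, t_res)
    counts = out.class_counts
    log.info(
        "labeled %d pairs: %d sensitive, %d resistant, %d unclear",
        len(df),
        counts[SENSITIVE],
        counts[RESISTANT],
        counts[UNCLEAR],
    )
    if counts[SENSITIVE] + counts[RESISTANT] == 0 and len(df):
        log.warning("no trainable pairs: every response fell in the unclear band")
    return out


@dataclass
class PairFeatures:
    """VSI design matrix for trainable pairs.

    Each row is [cell-similarity row | drug-similarity row]; y encodes the
    positive class (sensitive by default) as 1.
    """

    X: np.ndarray
    y: np.ndarray | None
    cell_ids: list[str]
    drug_ids: list[str]
    n_cell_features: int
    n_drug_features: int
    positive_label: str = SENSITIVE


def _rows_for(ids, sim_ids: list[str], values: np.ndarray, what: str) -> np.ndarray:
    index = {k: i for i, k in enumerate(sim_ids)}
    try:
        rows = [index[i] for i in ids]
    except KeyError as exc:
        raise ValidationError(f"unknown {what} ID {exc.args[0]!r} in pair set") from exc
    return values[rows]


def vsi_features(
    pairs: LabeledPairSet,
    cell_sim: SimilarityMatrix,
    drug_sim: SimilarityMatrix,
    positive_label: str = SENSITIVE,
) -> PairFeatures:
    """Featurize the sensitive/resistant pairs; unclear pairs are dropped."""
    df = pairs.trainable()
    X = np.hstack(
        [
            _rows_for(df["cell_id"], cell_sim.ids, cell_sim.values, "cell"),
            _rows_for(df["drug_id"], drug_sim.ids, drug_sim.values, "drug"),
        ]
    ) if len(df) else np.zeros((0, len(cell_sim.ids) + len(drug_sim.ids)))
    y = (df["label"] == positive_label).to_numpy(dtype=int)
    return PairFeatures(
        X,
        y,
        df["cell_id"].tolist(),
        df["drug_id"].tolist(),
        len(cell_sim.ids),
        len(drug_sim.ids),
        positive_label,
    )


def cross_vsi_features(
    pairs: pd.DataFrame,
    cell_rows: pd.DataFrame,
    drug_rows: pd.DataFrame,
) -> PairFeatures:
    """VSI features for held-out pairs from reference-anchored similarity rows.

    ``cell_rows`` / ``drug_rows`` are cross-similarity tables (query
    entities x training reference entities, as produced by
    :func:`methdrug.similarity.cross_similarity`); the feature length
    therefore matches the training design exactly.
    """
    cells = pairs["cell_id"].astype(str).tolist()
    drugs = pairs["drug_id"].astype(str).tolist()
    X = np.hstack(
        [
            _rows_for(cells, [str(i) for i in cell_rows.index], cell_rows.to_numpy(float), "cell"),
            _rows_for(drugs, [str(i) for i in drug_rows.index], drug_rows.to_numpy(float), "drug"),
        ]
    )
    return PairFeatures(X, None, cells, drugs, cell_rows.shape[1], drug_rows.shape[1])
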