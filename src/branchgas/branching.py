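"""Classify trajectory clusters into pre-, mid- and post-branching phases.

A cluster is *pre-branching* when its cells are spread over at least `rho`
lineages with nearly identical, early median pseudotimes; *post-branching*
when one lineage dominates (fraction >= dominant_frac) and the cluster sits
late on the trajectory; everything else along the bifurcation is *branching*.
"Early"/"late" are resolved against the global median pseudotime, which makes
the rule scale-free across datasets whose time spans differ.

A cell counts as lying on a lineage when its assignment weight for that
lineage is at least half its maximum weight, so cells on the shared trunk
(equal weights) count for every lineage they straddle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trajectory import CellClustering, LineageModel

logger = logging.getLogger(__name__)

PRE, BRANCHING, POST = "pre", "branching", "post"


@dataclass
class PhaseParams:
    """Thresholds of the phase rules.

    rho : minimum number of associated lineages for the multi-lineage test.
    theta : maximum spread of per-lineage median pseudotimes (on [0, 1]).
    assoc_frac : minimum fraction of a cluster's cells on a lineage for the
        lineage to count as associated.
    dominant_frac : fraction of cells on a single lineage that defines a
        post-branching majority.
    """

    rho: int = 2
    theta: float = 0.3
    assoc_frac: float = 0.2
    dominant_frac: float = 0.8

    def __post_init__(self):
        if self.theta <= 0 or self.rho < 1:
            raise ValueError("theta > 0 and rho >= 1 required")
        if not (0 < self.assoc_frac <= self.dominant_frac <= 1):
            raise ValueError("need 0 < assoc_frac <= dominant_frac <= 1")


@dataclass
class PhaseLabeling:
    phase: dict  # cluster id -> PRE | BRANCHING | POST
    evidence: dict = field(default_factory=dict)


def _cells_on_lineages(model: LineageModel):
    """Boolean cells x lineages membership: weight >= half the cell's max."""
    w = model.lineage_weights
    wmax = w.max(axis=1, keepdims=True)
    return (w >= 0.5 * wmax) & (wmax > 0)


def classify_phases(model: LineageModel, params: PhaseParams = None
                    ) -> PhaseLabeling:
    """Apply the pre/branching/post rules to every cluster on the bifurcation."""
    params = params or PhaseParams()
    if model.n_lineages < 2:
        raise ValueError("phase classification needs a bifurcation (>=2 lineages)")
    labels = model.cluster_labels
    on_lin = _cells_on_lineages(model)
    cell_pt = model.cell_pseudotime()
    on_any = on_lin.any(axis=1)
    global_median = float(np.median(cell_pt[on_any]))
    phase, evidence = {}, {}
    for c in sorted(set(labels.tolist())):
        in_c = labels == c
        n_c = int(in_c.sum())
        fracs = on_lin[in_c].sum(axis=0) / max(n_c, 1)
        associated = fracs >= params.assoc_frac
        medians = {}
        for li in range(model.n_lineages):
            sel = in_c & on_lin[:, li]
            if sel.any():
                medians[li] = float(np.median(model.pseudotime[sel, li]))
        if not associated.any():
            logger.warning("cluster %s lies off all bifurcation lineages", c)
            phase[c] = None
            continue
        assoc_meds = [medians[li] for li in np.flatnonzero(associated)
                      if li in medians]
        med_spread = (max(assoc_meds) - min(assoc_meds)) if len(assoc_meds) > 1 else 0.0
        cluster_median = float(np.median(cell_pt[in_c]))
        # dominance counts only cells committed to exactly one lineage, so
        # trunk cells (straddling the shared prefix) never look dominant
        exclusive = on_lin & (on_lin.sum(axis=1, keepdims=True) == 1)
        dominant = float(exclusive[in_c].sum(axis=0).max() / max(n_c, 1))
        evidence[c] = {
            "lineage_fractions": fracs.tolist(),
            "lineage_medians": medians,
            "median_spread": med_spread,
            "cluster_median": cluster_median,
            "global_median": global_median,
            "dominant_fraction": dominant,
        }
        if (int(associated.sum()) >= params.rho and med_spread < params.theta
                and cluster_median < global_median):
            phase[c] = PRE
        elif dominant >= params.dominant_frac and cluster_median >= global_median:
            phase[c] = POST
        else:
            phase[c] = BRANCHING
    return PhaseLabeling(phase=phase, evidence=evidence)


def phase_cells(labeling: PhaseLabeling, clustering: CellClustering,
                phase: str) -> np.ndarray:
    """Indices of the cells whose cluster carries `phase` (disjoint by phase)."""
    if phase not in (PRE, BRANCHING, POST):
        raise ValueError(f"unknown phase {phase!r}")
    clusters = [c for c, p in labeling.phase.items() if p == phase]
    mask = np.isin(clustering.labels, clusters)
    if not mask.any():
        logger.warning("no cells in phase %s", phase)
    return np.flatnonzero(mask)


class PhaseClassifier:
    """Thin estimator wrapper around `classify_phases`.

    Attributes after fit: labeling_, phase_ (cluster -> phase mapping).
    """

    def __init__(self, rho=2, theta=0.3, assoc_frac=0.2, dominant_frac=0.8):
        self.rho = rho
        self.theta = theta
        self.assoc_frac = assoc_frac
        self.dominant_frac = dominant_frac

    def get_params(self, deep=True):
        return {"rho": self.rho, "theta": self.theta,
                "assoc_frac": self.assoc_frac,
                "dominant_frac": self.dominant_frac}

    def set_params(self, **kw):
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, lineage_model: LineageModel):
        params = PhaseParams(rho=self.rho, theta=self.theta,
                             assoc_frac=self.assoc_frac,
                             dominant_frac=self.dominant_frac)
        self.labeling_ = classify_phases(lineage_model, params)
        self.phase_ = self.labeling_.phase
        return self
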