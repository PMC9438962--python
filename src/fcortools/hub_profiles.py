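"""Hub-level FCOR features and nonparametric group comparison.

Each connector hub contributes one mean raw FCOR value per network template
and per subject (5 hubs x 14 templates = 70 features in the canonical
configuration). Group differences per (hub, template) pair are tested with a
two-sided Wilcoxon rank-sum and Benjamini-Hochberg control across the joint
family of all pairs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .fcor import FcorMaps, bh_fdr
from .group_inference import ConnectorHub

log = logging.getLogger(__name__)


def feature_name(hub_label: str, network: str) -> str:
    return f"{hub_label}|{network}"


def extract_hub_features(fcor_maps: list[FcorMaps], hubs: list[ConnectorHub],
                         use_z: bool = False) -> pd.DataFrame:
    """Subjects x (hub x template) table of mean FCOR over each hub ROI.

    Raw FCOR values (in [0, 1]) are used by default; ``use_z=True`` switches
    to the z-scored maps.
    """
    if not hubs:
        raise ParameterError("no hubs given")
    if not fcor_maps:
        raise ParameterError("no subject FCOR maps given")
    names = fcor_maps[0].names
    rows = {}
    for maps in fcor_maps:
        if maps.names != names:
            raise ParameterError("subjects have inconsistent template sets")
        source = maps.z if use_z else maps.raw
        row = {}
        for hub in hubs:
            roi = np.asarray(hub.roi_voxels, dtype=int)
            if roi.size == 0:
                raise ParameterError(f"hub {hub.label} has an empty ROI")
            for j, net in enumerate(names):
                row[feature_name(hub.label, net)] = float(source[roi, j].mean())
        rows[maps.subject_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    return table


def ranksum_by_network(features: pd.DataFrame, groups: np.ndarray,
                       q: float = 0.05) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per feature column with joint BH control.

    ``groups`` aligns with the rows of ``features``. Ties are handled by
    midranks with the normal approximation and tie correction. Zero-variance
    columns get p = 1 and are flagged.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != features.shape[0]:
        raise ParameterError("groups must align with feature rows")
    pat = features.loc[groups == "patient"]
    ctl = features.loc[groups == "control"]
    if len(pat) < 2 or len(ctl) < 2:
        raise ParameterError("both groups need at least 2 subjects")
    records = []
    for col in features.columns:
        x, y = pat[col].to_numpy(float), ctl[col].to_numpy(float)
        degenerate = np.ptp(np.concatenate([x, y])) == 0
        if degenerate:
            u, p = float(len(x) * len(y) / 2), 1.0
            log.warning("feature %s has zero variance; p set to 1", col)
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
            u, p = float(res.statistic), float(res.pvalue)
        hub, _, net = col.partition("|")
        records.append({"hub": hub, "network": net, "feature": col,
                        "statistic": u, "p": p, "degenerate": degenerate})
    table = pd.DataFrame(records)
    table["significant"] = bh_fdr(table["p"].to_numpy(), q)
    table.attrs["q"] = q
    table.attrs["family"] = "all hub x template pairs jointly"
    return table
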