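"""Mapping of similarity edges onto the seven von Economo-Koskinas
cytoarchitectural classes and the two summary statistics built on it.

The seven classes group cortical regions by laminar structure: primary motor
cortex (PMC), primary sensory cortex (PSC), secondary sensory cortex (SSC),
association cortex 1 and 2 (AC1, AC2), limbic regions (LIMB), and the
insular cortex (INS).  The Desikan-Killiany-to-class table ships as an
editable CSV asset assembled from standard literature assignments (the
classes themselves are anatomical conventions, and any 34-row table with the
same columns can be substituted).

Two statistics summarize where significant similarity edges live:

* inter-regional similarity proportion - a symmetric 7x7 matrix giving the
  percentage of significant edges joining each unordered class pair;
* regional contribution - a 7-vector giving the percentage of significant
  edge endpoints falling in each class (a within-class edge contributes both
  endpoints to its class), so the vector sums to 100%.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .synthetic_cohort import CYTOARCH_CLASSES

CLASS_INDEX = {c: i for i, c in enumerate(CYTOARCH_CLASSES)}


def _strip_hemisphere(region: str) -> str:
    for prefix in ("lh_", "rh_", "lh.", "rh."):
        if region.startswith(prefix):
            return region[len(prefix):]
    return region


def load_cytoarch_map(
    atlas: list[str], mapping_csv: str | None = None
) -> dict[str, str]:
    """Class label for every atlas region; bilateral homologues share a class.

    ``atlas`` uses the packaged Desikan-Killiany names (optionally prefixed
    ``lh_``/``rh_``).  Unmapped regions raise, listing the offenders.
    """
    if mapping_csv is None:
        mapping_csv = str(resources.files("brainsim.data") / "dk68_von_economo.csv")
    table = pd.read_csv(mapping_csv)
    base_map = dict(zip(table["region"], table["cytoarch_class"]))
    bad_classes = sorted(set(base_map.values()) - set(CYTOARCH_CLASSES))
    if bad_classes:
        raise ValueError(f"mapping file contains unknown classes: {bad_classes}")
    out: dict[str, str] = {}
    missing = []
    for region in atlas:
        base = _strip_hemisphere(region)
        if base in base_map:
            out[region] = base_map[base]
        else:
            missing.append(region)
    if missing:
        raise ValueError(f"regions not present in the cytoarchitectural map: {missing}")
    return out


def _edge_classes(
    sig_edges: list[tuple[str, str]], mapping: dict[str, str]
) -> list[tuple[int, int]]:
    out = []
    for r1, r2 in sig_edges:
        for r in (r1, r2):
            if r not in mapping:
                raise ValueError(f"region {r!r} missing from the cytoarchitectural map")
        c1, c2 = CLASS_INDEX[mapping[r1]], CLASS_INDEX[mapping[r2]]
        out.append((min(c1, c2), max(c1, c2)))
    return out


def edge_class_proportions(
    sig_edges: list[tuple[str, str]], mapping: dict[str, str]
) -> pd.DataFrame:
    """Symmetric 7x7 matrix of percentages over unordered class pairs."""
    if not sig_edges:
        raise ValueError("no significant edges to summarize")
    counts = np.zeros((7, 7))
    for c1, c2 in _edge_classes(sig_edges, mapping):
        counts[c1, c2] += 1
        if c1 != c2:
            counts[c2, c1] += 1
    pct = 100.0 * counts / len(sig_edges)
    return pd.DataFrame(pct, index=CYTOARCH_CLASSES, columns=CYTOARCH_CLASSES)


def regional_contribution(
    sig_edges: list[tuple[str, str]], mapping: dict[str, str]
) -> pd.Series:
    """Percentage of significant edge endpoints per class (sums to 100)."""
    if not sig_edges:
        raise ValueError("no significant edges to summarize")
    counts = np.zeros(7)
    for c1, c2 in _edge_classes(sig_edges, mapping):
        counts[c1] += 1
        counts[c2] += 1
    pct = 100.0 * counts / (2 * len(sig_edges))
    return pd.Series(pct, index=CYTOARCH_CLASSES, name="contribution_pct")


def edges_from_feature_ids(feature_ids: list[str]) -> list[tuple[str, str]]:
    """Parse 'region_i|region_j' edge feature ids into region pairs."""
    out = []
    for fid in feature_ids:
        parts = fid.split("|")
        if len(parts) != 2:
            raise ValueError(f"feature id {fid!r} is not an edge name")
        out.append((parts[0], parts[1]))
    return out
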