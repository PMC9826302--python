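"""Per-genus and clade-level climatic profiles.

A climatic profile is the percentage distribution of a taxon's occurrences
over the categories of one regionalization. A taxon is *unequivocally
assigned* to a category when strictly more than 75% of its unique-coordinate
occurrences fall in it; otherwise the assignment is "equivocal".
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Regionalization

EQUIVOCAL = "equivocal"


@dataclass
class ClimaticProfile:
    taxon: str
    classification: str
    shares: dict  # category -> percentage (0-100)
    n_used: int
    n_unclassified: int
    assignment: str

    def to_rows(self):
        return [{"taxon": self.taxon, "classification": self.classification,
                 "category": cat, "share": share, "n_used": self.n_used}
                for cat, share in sorted(self.shares.items())]


def _profile_from_categories(categories, taxon, layer_name,
                             threshold: float) -> ClimaticProfile:
    counts = Counter(categories)
    n_unclassified = counts.pop(Regionalization.UNCLASSIFIED, 0)
    n_used = sum(counts.values())
    if n_used == 0:
        raise ValueError(f"no classifiable records for {taxon!r}")
    shares = {cat: 100.0 * c / n_used for cat, c in counts.items()}
    assignment = EQUIVOCAL
    for cat, share in shares.items():
        if share > 100.0 * threshold:
            assignment = cat
            break
    return ClimaticProfile(taxon, layer_name, shares, n_used,
                           n_unclassified, assignment)


def genus_profile(records, layer: Regionalization,
                  threshold: float = 0.75) -> ClimaticProfile:
    """Climatic profile of one genus on one regionalization.

    Records are first reduced to one per exact (longitude, latitude)
    coordinate to dampen local resampling bias; points in NoData cells are
    excluded from the percentage denominator but reported. The assignment is
    the category holding strictly more than ``threshold`` of the share, else
    "equivocal" (75.00% exactly is equivocal).
    """
    if not records:
        raise ValueError("genus_profile needs at least one record")
    genus = records[0].genus
    seen, points = set(), []
    for rec in records:
        key = (rec.longitude, rec.latitude)
        if key not in seen:
            seen.add(key)
            points.append(key)
    cats = layer.sample([p[0] for p in points], [p[1] for p in points])
    return _profile_from_categories(cats, genus, layer.name, threshold)


def regular_subsample(records, target: int = 1000, seed: int = 0):
    """Spatially regular subsample of a genus's records.

    A systematic grid of approximately ``target`` nodes is laid over the
    records' bounding box and the record nearest each node is taken; the
    yield is adjusted to exactly ``target`` by dropping the picks farthest
    from their nodes or adding the closest unused records. Deterministic
    given the seed (which only jitters the grid origin). Inputs with at most
    ``target`` records are returned unchanged.
    """
    records = list(records)
    n = len(records)
    if n <= target:
        return records
    rng = np.random.default_rng(seed)
    lon = np.array([r.longitude for r in records])
    lat = np.array([r.latitude for r in records])
    xmin, xmax = lon.min(), lon.max()
    ymin, ymax = lat.min(), lat.max()
    w = max(xmax - xmin, 1e-9)
    h = max(ymax - ymin, 1e-9)
    # grid aspect ratio follows the bounding box
    ny = max(1, int(round(np.sqrt(target * h / w))))
    nx = max(1, int(np.ceil(target / ny)))
    ox, oy = rng.random(2)  # deterministic origin jitter within one mesh
    gx = xmin + (np.arange(nx) + ox) * (w / nx)
    gy = ymin + (np.arange(ny) + oy) * (h / ny)
    nodes = np.array([(x, y) for x in gx for y in gy])

    # nearest unused record to each node, in node order
    used = np.zeros(n, dtype=bool)
    picks = []  # (distance to node, record index)
    for node in nodes:
        d2 = (lon - node[0]) ** 2 + (lat - node[1]) ** 2
        d2[used] = np.inf
        j = int(np.argmin(d2))
        if np.isfinite(d2[j]):
            used[j] = True
            picks.append((float(d2[j]), j))
    if len(picks) > target:
        picks.sort(key=lambda t: (t[0], t[1]))  # drop farthest-from-node picks
        picks = picks[:target]
    elif len(picks) < target:
        # top up with unused records closest to any node (stable order)
        remaining = np.where(~used)[0]
        dmin = np.array([
            ((lon[i] - nodes[:, 0]) ** 2 + (lat[i] - nodes[:, 1]) ** 2).min()
            for i in remaining])
        order = remaining[np.lexsort((remaining, dmin))]
        for i in order[: target - len(picks)]:
            picks.append((0.0, int(i)))
    idx = sorted(j for _, j in picks)
    return [records[j] for j in idx]


def clade_profile(records, layer: Regionalization, oversample_cap: int = 1500,
                  target: int = 1000, seed: int = 0,
                  threshold: float = 0.75) -> ClimaticProfile:
    """Pooled climatic profile of a whole clade.

    Genera with strictly more than ``oversample_cap`` records are reduced to
    ``target`` records by regular spatial subsampling before pooling, so
    heavily collected genera do not dominate the clade-level percentages.
    Unlike the per-genus profile, pooling does not deduplicate coordinates
    across genera.
    """
    by_genus = {}
    for rec in records:
        by_genus.setdefault(rec.genus, []).append(rec)
    if not by_genus:
        raise ValueError("clade_profile needs at least one genus")
    pooled = []
    for genus in sorted(by_genus):
        recs = by_genus[genus]
        if len(recs) > oversample_cap:
            recs = regular_subsample(recs, target=target, seed=seed)
        pooled.extend(recs)
    cats = layer.sample([r.longitude for r in pooled],
                        [r.latitude for r in pooled])
    return _profile_from_categories(cats, "CLADE", layer.name, threshold)


def compare_to_qualitative(profiles, labels, merge_rules=None) -> pd.DataFrame:
    """Compare semiquantitative assignments with qualitative labels.

    ``labels`` maps genus -> qualitative label (tropical / temperate);
    ``merge_rules`` maps a profile category to the broader category it counts
    as (e.g. subtropical -> tropical, "warm temperate" -> temperate). Each
    genus is scored "agree", "agree-after-merge", "equivocal" or "disagree".
    """
    merge_rules = merge_rules or {}
    rows = []
    for prof in profiles:
        if prof.taxon not in labels:
            raise KeyError(f"no qualitative label for genus {prof.taxon!r}")
        label = labels[prof.taxon]
        if prof.assignment == EQUIVOCAL:
            outcome = "equivocal"
        elif prof.assignment == label:
            outcome = "agree"
        elif merge_rules.get(prof.assignment, prof.assignment) == label:
            outcome = "agree-after-merge"
        else:
            outcome = "disagree"
        rows.append({"taxon": prof.taxon, "classification": prof.classification,
                     "label": label, "assignment": prof.assignment,
                     "outcome": outcome})
    return pd.DataFrame(rows)


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Long-format table (taxon, classification, category, share, n_used)."""
    rows = []
    for p in profiles:
        rows.extend(p.to_rows())
    return pd.DataFrame(rows)


def write_profiles(profiles, csv_path, json_path=None):
    profiles_to_frame(profiles).to_csv(csv_path, index=False)
    if json_path is not None:
        summary = [{"taxon": p.taxon, "classification": p.classification,
                    "shares": p.shares, "n_used": p.n_used,
                    "n_unclassified": p.n_unclassified,
                    "assignment": p.assignment} for p in profiles]
        Path(json_path).write_text(json.dumps(summary, indent=2))
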