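"""Symptom instrument, cohort container, and network serialization.

The data model mirrors a clinician-rated depression instrument (HRSD-17
style): 17 ordinal items, most scored 0-4 with four items scored 0-2, plus
a binary remission outcome and an optional binary study indicator used as a
moderator. Cohorts are plain delimited text files with a header row; fitted
networks are serialized as edge-list JSON or GraphML.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger("netoutcome")

OUTCOME_COL = "remission"
MODERATOR_COL = "study"
ID_COL = "id"


class SchemaError(ValueError):
    """Cohort file columns do not match the expected instrument schema."""


class ValidationError(ValueError):
    """Cohort values violate a range or type invariant."""


@dataclass(frozen=True)
class ItemDescriptor:
    """One instrument item: a label and its admissible integer score range."""

    label: str
    min_score: int = 0
    max_score: int = 4

    def __post_init__(self) -> None:
        if self.min_score != 0:
            raise ValidationError(f"item {self.label!r}: min_score must be 0")
        if self.max_score not in (2, 4):
            raise ValidationError(
                f"item {self.label!r}: max_score must be 2 or 4, got {self.max_score}"
            )


@dataclass(frozen=True)
class SymptomScale:
    """An ordered collection of item descriptors with unique labels."""

    items: tuple[ItemDescriptor, ...]

    def __post_init__(self) -> None:
        labels = [it.label for it in self.items]
        if len(set(labels)) != len(labels):
            raise ValidationError("item labels must be unique")
        if not self.items:
            raise ValidationError("scale must have at least one item")

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_scores(self) -> np.ndarray:
        return np.array([it.max_score for it in self.items], dtype=float)


#: Standard 17-item ordering; the four 0-2 items are general somatic
#: symptoms, genital symptoms, weight loss, and insight.
_HRSD17_ITEMS: tuple[tuple[str, int], ...] = (
    ("depressed_mood", 4),
    ("guilt", 4),
    ("suicidality", 4),
    ("insomnia_early", 4),
    ("insomnia_middle", 4),
    ("insomnia_late", 4),
    ("work_activities", 4),
    ("retardation", 4),
    ("agitation", 4),
    ("anxiety_psychic", 4),
    ("anxiety_somatic", 4),
    ("somatic_gastrointestinal", 4),
    ("somatic_general", 2),
    ("genital_symptoms", 2),
    ("hypochondriasis", 4),
    ("weight_loss", 2),
    ("insight", 2),
)

SUICIDALITY = 2
RETARDATION = 7
HYPOCHONDRIASIS = 14


def hrsd17() -> SymptomScale:
    """The default 17-item depression scale (13 items 0-4, four items 0-2)."""
    return SymptomScale(
        tuple(ItemDescriptor(lbl, 0, mx) for lbl, mx in _HRSD17_ITEMS)
    )


@dataclass
class CohortTable:
    """Validated patients x (items, outcome, optional moderator) table.

    ``scores`` is float-valued; when ``discrete`` is True every entry must be
    an integer inside its item's score range. Non-discretized synthetic
    cohorts (latent continuous symptoms) set ``discrete=False`` and skip the
    range check.
    """

    scores: np.ndarray
    outcome: np.ndarray
    scale: SymptomScale
    moderator: np.ndarray | None = None
    ids: np.ndarray | None = None
    n_dropped: int = 0
    discrete: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.outcome = np.asarray(self.outcome)
        if self.scores.ndim != 2:
            raise ValidationError("scores must be a 2-D matrix")
        n, p = self.scores.shape
        if n < 1:
            raise ValidationError("empty cohort: at least one patient required")
        if p != self.scale.n_items:
            raise ValidationError(
                f"scores have {p} columns but scale has {self.scale.n_items} items"
            )
        if self.outcome.shape != (n,):
            raise ValidationError("outcome length must match number of patients")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValidationError("outcome must contain only 0/1")
        self.outcome = self.outcome.astype(int)
        if self.moderator is not None:
            self.moderator = np.asarray(self.moderator)
            if self.moderator.shape != (n,):
                raise ValidationError("moderator length must match number of patients")
            if not np.isin(self.moderator, (0, 1)).all():
                raise ValidationError("moderator must contain only 0/1")
            self.moderator = self.moderator.astype(int)
        if self.discrete:
            self._check_ranges()

    def _check_ranges(self) -> None:
        for j, item in enumerate(self.scale.items):
            col = self.scores[:, j]
            if not np.all(col == np.round(col)):
                bad = int(np.flatnonzero(col != np.round(col))[0])
                raise ValidationError(
                    f"row {bad}, item {item.label!r}: non-integer score {col[bad]}"
                )
            out = (col < item.min_score) | (col > item.max_score)
            if out.any():
                bad = int(np.flatnonzero(out)[0])
                raise ValidationError(
                    f"row {bad}, item {item.label!r}: score {col[bad]:g} outside "
                    f"[{item.min_score}, {item.max_score}]"
                )

    @property
    def n_patients(self) -> int:
        return self.scores.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.scale.labels)
        if self.discrete:
            df = df.astype(int)
        df[OUTCOME_COL] = self.outcome
        if self.moderator is not None:
            df[MODERATOR_COL] = self.moderator
        if self.ids is not None:
            df.insert(0, ID_COL, self.ids)
        return df

    def subset(self, idx: np.ndarray) -> "CohortTable":
        """Row-subset (used by bootstrap resampling); keeps metadata."""
        return CohortTable(
            scores=self.scores[idx],
            outcome=self.outcome[idx],
            scale=self.scale,
            moderator=None if self.moderator is None else self.moderator[idx],
            ids=None if self.ids is None else np.asarray(self.ids)[idx],
            discrete=self.discrete,
        )


def load_cohort(
    path,
    scale: SymptomScale | None = None,
    *,
    delimiter: str = ",",
    require_moderator: bool = False,
) -> CohortTable:
    """Read a delimited cohort file and return a validated :class:`CohortTable`.

    Rows with any missing item or outcome value (or missing moderator when
    ``require_moderator``) are dropped (complete-case analysis); the number
    of dropped rows is logged and stored on the returned table.
    """
    scale = scale or hrsd17()
    df = pd.read_csv(path, sep=delimiter)
    expected = set(scale.labels) | {OUTCOME_COL}
    optional = {MODERATOR_COL, ID_COL}
    missing = expected - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    unknown = set(df.columns) - expected - optional
    if unknown:
        raise SchemaError(f"unknown columns: {sorted(unknown)}")
    if len(df) == 0:
        raise ValidationError("empty cohort: file has no data rows")

    has_mod = MODERATOR_COL in df.columns
    check_cols = scale.labels + [OUTCOME_COL]
    if has_mod and require_moderator:
        check_cols.append(MODERATOR_COL)
    complete = df[check_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("load_cohort: dropped %d incomplete rows (complete-case)", n_dropped)
    df = df[complete]
    if len(df) == 0:
        raise ValidationError("empty cohort: all rows incomplete")
    if require_moderator and not has_mod:
        raise SchemaError(f"moderator column {MODERATOR_COL!r} required but absent")

    moderator = None
    if has_mod:
        mod = df[MODERATOR_COL]
        if mod.notna().all():
            moderator = mod.to_numpy()
    table = CohortTable(
        scores=df[scale.labels].to_numpy(dtype=float),
        outcome=df[OUTCOME_COL].to_numpy(),
        scale=scale,
        moderator=moderator,
        ids=df[ID_COL].to_numpy() if ID_COL in df.columns else None,
        n_dropped=n_dropped,
    )
    return table


def write_cohort(table: CohortTable, path, *, delimiter: str = ",") -> None:
    table.to_dataframe().to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Network serialization (edge-list JSON and GraphML)
# ---------------------------------------------------------------------------

def _model_record(model) -> dict:
    adj = np.asarray(model.adjacency)
    undef = getattr(model, "sign_undefined", None)
    nodes = [
        {
            "id": i,
            "label": lbl,
            "type": model.node_types[i],
            "predictability": float(model.predictability[i]),
        }
        for i, lbl in enumerate(model.node_labels)
    ]
    edges = []
    for i in range(adj.shape[0]):
        for j in range(i + 1, adj.shape[1]):
            if adj[i, j] != 0.0:
                edges.append(
                    {
                        "source": i,
                        "target": j,
                        "weight": float(adj[i, j]),
                        "sign_undefined": bool(undef[i, j]) if undef is not None else False,
                    }
                )
    srw = model.smallest_retained_weight
    return {
        "nodes": nodes,
        "edges": edges,
        "smallest_retained_weight": None if srw is None else float(srw),
    }


def write_network(model, path, format: str = "json") -> None:
    """Serialize a fitted network (nodes, signed weighted edges, predictability).

    ``format`` is ``"json"`` (edge-list JSON) or ``"graphml"``. Weights
    round-trip at full double precision.
    """
    rec = _model_record(model)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rec, fh, indent=1)
    elif format == "graphml":
        g = nx.Graph(smallest_retained_weight=float(rec["smallest_retained_weight"] or 0.0))
        for node in rec["nodes"]:
            g.add_node(
                node["id"],
                label=node["label"],
                type=node["type"],
                predictability=node["predictability"],
            )
        for e in rec["edges"]:
            g.add_edge(
                e["source"],
                e["target"],
                weight=e["weight"],
                sign_undefined=int(e["sign_undefined"]),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path, format: str = "json"):
    """Read a serialized network back into a (fit-free) ``NetworkModel``."""
    from .estimate import NetworkModel  # local import avoids a cycle

    if format == "json":
        with open(path, encoding="utf-8") as fh:
            rec = json.load(fh)
        nodes = sorted(rec["nodes"], key=lambda d: d["id"])
        m = len(nodes)
        adj = np.zeros((m, m))
        undef = np.zeros((m, m), dtype=bool)
        for e in rec["edges"]:
            i, j = e["source"], e["target"]
            adj[i, j] = adj[j, i] = e["weight"]
            undef[i, j] = undef[j, i] = e.get("sign_undefined", False)
        return NetworkModel(
            node_labels=[d["label"] for d in nodes],
            node_types=[d["type"] for d in nodes],
            adjacency=adj,
            sign_undefined=undef,
            nodewise_fits=None,
            predictability=np.array([d["predictability"] for d in nodes]),
            smallest_retained_weight=rec.get("smallest_retained_weight"),
        )
    if format == "graphml":
        g = nx.read_graphml(path)
        ids = sorted(g.nodes, key=lambda x: int(x))
        m = len(ids)
        adj = np.zeros((m, m))
        undef = np.zeros((m, m), dtype=bool)
        for u, v, d in g.edges(data=True):
            i, j = int(u), int(v)
            adj[i, j] = adj[j, i] = float(d["weight"])
            undef[i, j] = undef[j, i] = bool(int(d.get("sign_undefined", 0)))
        srw = g.graph.get("smallest_retained_weight")
        return NetworkModel(
            node_labels=[g.nodes[i]["label"] for i in ids],
            node_types=[g.nodes[i]["type"] for i in ids],
            adjacency=adj,
            sign_undefined=undef,
            nodewise_fits=None,
            predictability=np.array([float(g.nodes[i]["predictability"]) for i in ids]),
            smallest_retained_weight=None if srw in (None, 0.0) and not np.any(adj) else srw,
        )
    raise ValueError(f"unknown format {format!r}")
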