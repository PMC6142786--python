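"""In-memory four-layer ontology for EEG/sleep bookkeeping.

The store organizes everything the staging pipeline knows into a
domain -> category -> class -> instance hierarchy (e.g. domain
"EEG-based automatic sleep staging", categories EEG and Sleep, classes
participants / electrodes / features / sleep staging / staging rules).
Instances are linked by object properties (``hasEEGfeature``,
``hasSleepStages``, ``isCollected``) and annotated with typed data
properties (``hasAge`` Integer, ``hasGender`` String, one property per
extracted feature value).  Queries are conjunctive pattern matches over
class membership and property constraints, returned in insertion order.

The store serializes to JSON; reasoning/inference is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .epoch_io import META_COLUMNS, SCHEME_LABELS
from .errors import OntologyError

_DTYPE_CASTS = {
    "Integer": int,
    "Float": float,
    "String": str,
    "Boolean": bool,
}


@dataclass
class OntologyStore:
    domain_name: str = "EEG-based automatic sleep staging"
    categories: list = field(default_factory=list)
    classes: dict = field(default_factory=dict)    # class -> category
    instances: dict = field(default_factory=dict)  # instance -> class
    object_properties: list = field(default_factory=list)  # (subj, prop, obj)
    data_properties: list = field(default_factory=list)    # (subj, prop, value, dtype)
    # O(1) lookup indexes (kept in sync with the triple lists)
    _object_set: set = field(default_factory=set, repr=False)
    _data_index: dict = field(default_factory=dict, repr=False)  # (subj, prop) -> pos

    # -- hierarchy ----------------------------------------------------------

    def add_category(self, name: str) -> "OntologyStore":
        if name in self.categories:
            raise OntologyError(f"duplicate category {name!r}")
        self.categories.append(name)
        return self

    def add_class(self, name: str, category: str) -> "OntologyStore":
        if category not in self.categories:
            raise OntologyError(f"unknown category {category!r}")
        if name in self.classes:
            raise OntologyError(f"duplicate class {name!r}")
        self.classes[name] = category
        return self

    def add_instance(self, name: str, cls: str) -> "OntologyStore":
        if cls not in self.classes:
            raise OntologyError(f"unknown class {cls!r}")
        if name in self.instances:
            raise OntologyError(f"duplicate instance {name!r}")
        self.instances[name] = cls
        return self

    # -- properties ---------------------------------------------------------

    def set_object_property(self, subj: str, prop: str, obj: str) -> "OntologyStore":
        for inst in (subj, obj):
            if inst not in self.instances:
                raise OntologyError(f"unknown instance {inst!r}")
        triple = (subj, prop, obj)
        if triple not in self._object_set:
            self.object_properties.append(triple)
            self._object_set.add(triple)
        return self

    def set_data_property(
        self, subj: str, prop: str, value, dtype: str = "Float"
    ) -> "OntologyStore":
        if subj not in self.instances:
            raise OntologyError(f"unknown instance {subj!r}")
        if dtype not in _DTYPE_CASTS:
            raise OntologyError(f"unknown data type {dtype!r}")
        try:
            if dtype == "Integer" and not float(value).is_integer():
                raise ValueError
            if dtype == "Boolean" and not isinstance(value, bool):
                raise ValueError
            typed = _DTYPE_CASTS[dtype](value)
        except (TypeError, ValueError):
            raise OntologyError(
                f"value {value!r} does not parse as {dtype} for property {prop!r}"
            )
        key = (subj, prop)
        if key in self._data_index:  # overwrite in place, original position
            self.data_properties[self._data_index[key]] = (subj, prop, typed, dtype)
        else:
            self._data_index[key] = len(self.data_properties)
            self.data_properties.append((subj, prop, typed, dtype))
        return self

    def get_data_property(self, subj: str, prop: str):
        pos = self._data_index.get((subj, prop))
        return self.data_properties[pos][2] if pos is not None else None

    # -- querying -----------------------------------------------------------

    def query(self, cls: str | None = None, prop: str | None = None, value=None) -> list:
        """Instances matching every supplied constraint, insertion order.

        ``prop``/``value`` match either a data property (value equality) or
        an object property (object name equality); ``value=None`` with
        ``prop`` set matches any instance carrying the property.
        """
        result = list(self.instances)
        if cls is not None:
            result = [i for i in result if self.instances[i] == cls]
        if prop is not None:
            matches = set()
            for s, p, v, _ in self.data_properties:
                if p == prop and (value is None or v == value):
                    matches.add(s)
            for s, p, o in self.object_properties:
                if p == prop and (value is None or o == value):
                    matches.add(s)
            result = [i for i in result if i in matches]
        return result

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "domain_name": self.domain_name,
                "categories": self.categories,
                "classes": self.classes,
                "instances": self.instances,
                "object_properties": self.object_properties,
                "data_properties": self.data_properties,
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str) -> "OntologyStore":
        raw = json.loads(doc)
        store = cls(domain_name=raw["domain_name"])
        store.categories = list(raw["categories"])
        store.classes = dict(raw["classes"])
        store.instances = dict(raw["instances"])
        store.object_properties = [tuple(t) for t in raw["object_properties"]]
        store.data_properties = [tuple(t) for t in raw["data_properties"]]
        store._object_set = set(store.object_properties)
        store._data_index = {
            (s, p): i for i, (s, p, _, _) in enumerate(store.data_properties)
        }
        return store


def bootstrap_schema() -> OntologyStore:
    """Top-down construction of the fixed schema: EEG and Sleep categories
    and their classes, plus the staging-rule instances (the five stage
    combination schemes) and the two electrodes."""
    store = OntologyStore()
    store.add_category("EEG").add_category("Sleep")
    for cls in ("participants", "electrodes", "features"):
        store.add_class(cls, "EEG")
    for cls in ("sleep staging", "staging rules"):
        store.add_class(cls, "Sleep")
    for electrode in ("Fpz-Cz", "Pz-Oz"):
        store.add_instance(electrode, "electrodes")
    for scheme in SCHEME_LABELS:
        store.add_instance(f"{scheme}-state", "staging rules")
    return store


def ingest_feature_matrix(
    store: OntologyStore, matrix: pd.DataFrame, meta: list
) -> OntologyStore:
    """Load a feature table and subject metadata into the store.

    One instance per epoch under "sleep staging", linked to one feature
    instance per feature name via ``hasEEGfeature`` and carrying the 60
    feature values as Float data properties; one instance per participant
    with hasAge / hasGender / hasHealthStatus.
    """
    meta_by_id = {m.subject_id: m for m in meta}
    missing = set(matrix["subject_id"]) - set(meta_by_id)
    if missing:
        raise OntologyError(f"no metadata for subjects {sorted(missing)}")
    feature_cols = [c for c in matrix.columns if c not in META_COLUMNS]
    for name in feature_cols:
        if name not in store.instances:
            store.add_instance(name, "features")
    for m in meta_by_id.values():
        if m.subject_id not in store.instances:
            store.add_instance(m.subject_id, "participants")
            store.set_data_property(m.subject_id, "hasAge", m.age, "Integer")
            store.set_data_property(m.subject_id, "hasGender", m.gender, "String")
            store.set_data_property(m.subject_id, "hasHealthStatus", m.health_status, "String")
    for _, row in matrix.iterrows():
        eid = str(row["epoch_id"])
        store.add_instance(eid, "sleep staging")
        store.set_object_property(eid, "belongsTo", str(row["subject_id"]))
        store.set_data_property(eid, "hasSleepStages", str(row["stage"]), "String")
        store.set_data_property(eid, "hasGender", str(row["gender"]), "String")
        for name in feature_cols:
            store.set_object_property(eid, "hasEEGfeature", name)
            store.set_data_property(eid, name, float(row[name]), "Float")
    return store


def export_feature_matrix(store: OntologyStore, feature_names: list) -> pd.DataFrame:
    """Inverse of :func:`ingest_feature_matrix` (epoch rows, same values)."""
    rows = []
    for eid in store.query(cls="sleep staging"):
        row = {name: store.get_data_property(eid, name) for name in feature_names}
        row["stage"] = store.get_data_property(eid, "hasSleepStages")
        row["gender"] = store.get_data_property(eid, "hasGender")
        subj = [o for s, p, o in store.object_properties
                if s == eid and p == "belongsTo"]
        row["subject_id"] = subj[0] if subj else ""
        row["epoch_id"] = eid
        rows.append(row)
    return pd.DataFrame(rows, columns=feature_names + list(META_COLUMNS))
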