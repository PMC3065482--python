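"""Trial-table and graph serialization, plus study configuration.

Formats:

* trial CSV — columns ``trial_id,year,group,disease,treatment,hr,p_value``
  with a required header; validation errors name the offending data row;
* graphs — GraphML (lossless: carries provenance attributes and isolated
  nodes) and a two-column tab-separated edge list whose ``#``-comment
  header carries provenance (isolates cannot survive an edge list);
* study configuration — YAML mirroring :class:`StudyConfig`, with a full
  default file shipped as package data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .cohort import CohortConfig, HRModel, SignificanceModel, TrialCohort, TrialRecord
from .exceptions import ConfigurationError
from .networks import PAConfig

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials_csv",
    "write_trials_csv",
    "read_graph",
    "write_graph",
    "StudyConfig",
    "load_study_config",
    "default_study_yaml",
]

TRIAL_COLUMNS = ["trial_id", "year", "group", "disease", "treatment", "hr", "p_value"]


def write_trials_csv(cohort: TrialCohort, path) -> None:
    # %.17g guarantees the hr / p_value floats survive a read round-trip
    cohort.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trials_csv(path) -> TrialCohort:
    """Read and validate a trial table; returns a chronologically sorted cohort.

    Rows are validated one by one; the first invalid row is reported with
    its 1-based data row number. A missing ``trial_id`` column is filled
    from the row number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - {"trial_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if "trial_id" not in df.columns:
        df["trial_id"] = [f"R{i + 1}" for i in range(len(df))]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(TrialRecord(
                trial_id=str(row.trial_id), year=int(row.year),
                group=str(row.group), disease=str(row.disease),
                treatment=str(row.treatment), hr=float(row.hr),
                p_value=float(row.p_value),
            ))
        except (ValueError, TypeError) as e:
            raise ValueError(f"{path}: row {i}: {e}") from e
    return TrialCohort(records)


# --- graphs ----------------------------------------------------------------

_FORMATS = ("edgelist", "graphml")


def _infer_format(path: Path) -> str:
    if path.suffix == ".graphml":
        return "graphml"
    if path.suffix in (".edgelist", ".tsv", ".txt"):
        return "edgelist"
    raise ValueError(f"cannot infer graph format from {path.name!r}; "
                     f"pass fmt in {_FORMATS}")


def write_graph(g: nx.Graph, path, fmt: str | None = None) -> None:
    """Write a graph as GraphML or a provenance-commented edge list."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif fmt == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            for k in sorted(g.graph):
                fh.write(f"# {k}={g.graph[k]}\n")
            for u, v in g.edges():
                fh.write(f"{u}\t{v}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}; known: {_FORMATS}")


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text in ("True", "False"):
        return text == "True"
    return text


def read_graph(path, fmt: str | None = None) -> nx.Graph:
    """Read a graph written by :func:`write_graph`."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return g
    if fmt == "edgelist":
        g = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    g.graph[key.strip()] = _coerce(value)
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}: malformed edge line {line!r}")
                g.add_edge(parts[0], parts[1])
        return g
    raise ValueError(f"unknown graph format {fmt!r}; known: {_FORMATS}")


# --- study configuration ----------------------------------------------------

_DEFAULT_SUBSETS = (
    ("group", "disease"),
    ("group", "treatment"),
    ("disease", "treatment"),
    ("group", "disease", "treatment"),
)


@dataclass
class StudyConfig:
    """Everything a full study run needs; YAML-serializable.

    All randomness is derived from ``master_seed``; the per-stage seeds in
    ``cohort``/``pa`` are overridden by derived ones during a study run.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    pa: PAConfig = field(default_factory=PAConfig)
    attribute_subsets: tuple = _DEFAULT_SUBSETS
    er_replicates: int = 5
    bootstrap_replicates: int = 1000
    tail_min: int = 10
    n_bins: int = 20
    n_permutations: int = 10_000
    top_k: int = 10
    master_seed: int = 0
    output_dir: str = "study_output"
    trials_csv: str | None = None  # ingest instead of synthesizing

    def validate(self):
        if not self.attribute_subsets or any(not s for s in self.attribute_subsets):
            raise ConfigurationError("attribute_subsets must be non-empty subsets")
        if self.er_replicates < 1:
            raise ConfigurationError("er_replicates must be >= 1")
        self.cohort.validate()
        self.pa.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["attribute_subsets"] = [list(s) for s in self.attribute_subsets]
        d["cohort"]["attribute_frequencies"] = {
            k: dict(v) for k, v in self.cohort.attribute_frequencies.items()
        }
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "hr_model" in c:
                c["hr_model"] = HRModel(**c["hr_model"])
            if "significance_model" in c:
                c["significance_model"] = SignificanceModel(**c["significance_model"])
            if "year_range" in c:
                c["year_range"] = tuple(c["year_range"])
            d["cohort"] = CohortConfig(**c)
        if "pa" in d:
            d["pa"] = PAConfig(**d["pa"])
        if "attribute_subsets" in d:
            d["attribute_subsets"] = tuple(tuple(s) for s in d["attribute_subsets"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_study_config(path) -> StudyConfig:
    """Load a YAML study configuration."""
    with open(path, encoding="utf-8") as fh:
        return StudyConfig.from_dict(yaml.safe_load(fh) or {})


def default_study_yaml() -> str:
    """The shipped default study configuration, as YAML text."""
    return resources.files("trialnet").joinpath("data/study_default.yaml").read_text()
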