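"""End-to-end thermotolerant-candidate triage.

The mining workflow: score a sequence database against a family profile
HMM, annotate hits with measured OGT where a table maps them (predicted
thermophilicity otherwise), keep hits that are thermotolerant (OGT at or
above 50 C by default, or predicted thermophilic/hyperthermophilic) and
whose bit score falls strictly inside the score window configured for
their source database, then collapse hits whose mature sequences
(signal peptide removed) are identical, keeping the highest-scoring
representative.  Every input sequence appears exactly once in the report
with its per-filter outcomes; stage counts are logged for audit.

Score windows are configuration rather than constants: the shipped
defaults mirror the intent of ">100 bits from the curated database, <55
bits from the metagenome-derived one", but this package's bit scores are
not HMMER-calibrated, so windows should be set per deployment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError
from .phmm import ProfileHMM, hmm_search
from .thermoprot import TrainedModel, predict_thermophilicity

THERMOTOLERANT_CLASSES = {"thermophilic", "hyperthermophilic"}


@dataclass
class ScoreWindow:
    """Open interval (min, max) in bits; either endpoint may be unbounded."""

    min: float = float("-inf")
    max: float = float("inf")

    def __post_init__(self):
        if not self.min < self.max:
            raise ConfigError("score window requires min < max")

    def contains(self, score: float) -> bool:
        return self.min < score < self.max


@dataclass
class TriageConfig:
    score_windows: dict = field(default_factory=lambda: {
        "dbA": ScoreWindow(min=100.0),
        "dbB": ScoreWindow(max=55.0),
    })
    ogt_threshold: float = 50.0
    search_threshold: float = float("-inf")  # hmm_search floor, bits
    dedup: str = "exact_excluding_signal_peptide"
    seed: int = 0

    def __post_init__(self):
        for src, w in list(self.score_windows.items()):
            if isinstance(w, (tuple, list)):
                self.score_windows[src] = ScoreWindow(*w)
        if not (self.ogt_threshold == self.ogt_threshold):
            raise ConfigError("OGT threshold must be finite")


def map_ogt(hits, records_by_id: dict, ogt_table: dict,
            model: TrainedModel | None = None, threshold: float = 50.0) -> list[dict]:
    """Annotate hits with measured OGT or predicted thermophilicity.

    Mapped ids get thermotolerance = (OGT >= threshold), provenance
    "measured"; unmapped ids are classified with the ThermoProt-style model
    (provenance "predicted", thermotolerant when the predicted class is
    thermophilic or hyperthermophilic).
    """
    unmapped = [h for h in hits if h.id not in ogt_table]
    if unmapped and model is None:
        raise ConfigError(
            f"{len(unmapped)} hits lack OGT data and no classifier model was given"
        )
    predictions = {}
    if unmapped:
        preds = predict_thermophilicity(model, [records_by_id[h.id] for h in unmapped])
        predictions = {p["id"]: p for p in preds}
    annotated = []
    for h in hits:
        rec = records_by_id[h.id]
        row = {
            "id": h.id,
            "source": rec.source,
            "score": h.score,
            "ogt": None,
            "predicted_class": None,
            "predicted_score": None,
            "provenance": None,
            "thermotolerant": False,
        }
        if h.id in ogt_table:
            row["ogt"] = float(ogt_table[h.id])
            row["provenance"] = "measured"
            row["thermotolerant"] = row["ogt"] >= threshold
        else:
            p = predictions[h.id]
            row["predicted_class"] = p["label"]
            row["predicted_score"] = p["score"]
            row["provenance"] = "predicted"
            row["thermotolerant"] = p["label"] in THERMOTOLERANT_CLASSES
        annotated.append(row)
    return annotated


def apply_filters(annotated: list[dict], config: TriageConfig) -> list[dict]:
    """Thermotolerance AND strict score-window filters; rows gain pass flags."""
    out = []
    for row in annotated:
        src = row["source"]
        if src not in config.score_windows:
            raise ConfigError(f"no score window configured for source {src!r}")
        window = config.score_windows[src]
        row = dict(row)
        row["pass_thermotolerance"] = bool(row["thermotolerant"])
        row["pass_score_window"] = window.contains(row["score"])
        row["pass_all"] = row["pass_thermotolerance"] and row["pass_score_window"]
        out.append(row)
    return out


def dedup_candidates(filtered: list[dict], records_by_id: dict,
                     mode: str = "exact_excluding_signal_peptide") -> list[dict]:
    """Group rows with identical mature sequences; keep one representative.

    The mature sequence is everything after the annotated signal peptide
    (whole sequence when none).  The representative is the highest bit
    score, ties broken by lexicographic id.  Rows gain ``dedup_group`` and
    ``selected`` fields; group sizes sum to the number of filtered rows.
    """
    if mode != "exact_excluding_signal_peptide":
        raise ConfigError(f"unknown dedup mode {mode!r}")
    groups: dict[str, list] = {}
    for row in filtered:
        key = records_by_id[row["id"]].mature_residues
        groups.setdefault(key, []).append(row)
    out = []
    for gi, key in enumerate(sorted(groups)):
        members = sorted(groups[key], key=lambda r: (-r["score"], r["id"]))
        for j, row in enumerate(members):
            row = dict(row)
            row["dedup_group"] = gi
            row["selected"] = j == 0 and row["pass_all"]
            out.append(row)
    return out


REPORT_COLUMNS = [
    "id", "source", "score", "ogt", "predicted_class", "predicted_score",
    "provenance", "thermotolerant", "pass_thermotolerance", "pass_score_window",
    "pass_all", "dedup_group", "selected",
]


@dataclass
class CandidateReport:
    table: pd.DataFrame
    log: list  # stage-count dicts, JSON-lines serializable

    @property
    def selected_ids(self) -> list:
        return sorted(self.table.loc[self.table["selected"], "id"])

    def write(self, path, log_path=None):
        self.table.to_csv(path, sep="\t", index=False)
        if log_path:
            with open(log_path, "w") as fh:
                for entry in self.log:
                    fh.write(json.dumps(entry) + "\n")


def run_pipeline(seq_db, seed_alignment, ogt_table, model: TrainedModel | None,
                 config: TriageConfig, hmm: ProfileHMM | None = None) -> CandidateReport:
    """hmm_search -> map_ogt -> apply_filters -> dedup -> report.

    ``seq_db`` is the sequence collection to mine; ``seed_alignment`` the MSA
    of known family members (ignored when a prebuilt ``hmm`` is passed).
    Every input id appears exactly once in the report; non-hit sequences are
    reported with ``pass_all`` False.  Deterministic for fixed inputs.
    """
    seq_db = list(seq_db)
    records_by_id = {r.id: r for r in seq_db}
    if len(records_by_id) != len(seq_db):
        raise ConfigError("duplicate ids in the sequence database")
    from .phmm import build_phmm  # local import to avoid cycle at module load

    model_hmm = hmm if hmm is not None else build_phmm(seed_alignment)
    log = [{"stage": "input", "count": len(seq_db)}]

    hits = hmm_search(model_hmm, seq_db, config.search_threshold)
    log.append({"stage": "hmm_search", "count": len(hits),
                "threshold_bits": config.search_threshold})

    annotated = map_ogt(hits, records_by_id, ogt_table, model, config.ogt_threshold)
    log.append({
        "stage": "map_ogt",
        "count": len(annotated),
        "measured": sum(1 for a in annotated if a["provenance"] == "measured"),
        "predicted": sum(1 for a in annotated if a["provenance"] == "predicted"),
    })

    filtered = apply_filters(annotated, config)
    log.append({"stage": "apply_filters",
                "count": sum(1 for f in filtered if f["pass_all"])})

    deduped = dedup_candidates(filtered, records_by_id, config.dedup)
    log.append({"stage": "dedup",
                "groups": len({d["dedup_group"] for d in deduped}),
                "selected": sum(1 for d in deduped if d["selected"])})

    rows = {d["id"]: d for d in deduped}
    table_rows = []
    for rec in seq_db:
        if rec.id in rows:
            table_rows.append({c: rows[rec.id].get(c) for c in REPORT_COLUMNS})
        else:
            # below the search threshold: reported, never selectable
            table_rows.append({**{c: None for c in REPORT_COLUMNS},
                               "id": rec.id, "source": rec.source,
                               "thermotolerant": False,
                               "pass_all": False, "selected": False})
    table = pd.DataFrame(table_rows, columns=REPORT_COLUMNS)
    assert len(table) == len(seq_db)
    assert set(table.loc[table["selected"] == True, "id"]) <= \
        set(table.loc[table["pass_all"] == True, "id"])
    return CandidateReport(table=table, log=log)
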