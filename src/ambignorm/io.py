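"""Table I/O, validation, and reproducible pipeline runs.

All tables are UTF-8 TSV (tab-separated avoids quoting commas inside
zeugma sentences); zeugma items travel as JSONL with 0-based half-open
character offsets.  Readers tolerate CRLF line endings and a UTF-8 BOM,
validate headers against the documented schemas, collect malformed rows
into an error report, and abort when the malformed fraction exceeds a
configurable cap.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ambignorm import __version__
from ambignorm.nlm_metrics import ZeugmaItem

#: column -> dtype coercion for each documented table
SCHEMAS: dict[str, dict[str, type]] = {
    "associates": {"participant_id": str, "word": str, "slot": int, "response": str},
    "assignments": {
        "rater_id": str, "participant_id": str, "word": str, "slot": int, "label": int,
    },
    "ratings": {"participant_id": str, "item": str, "rating": int},
    "items": {"item": str, "condition": str},
}


class SchemaError(ValueError):
    """Header or row-level violation of a documented table schema."""


@dataclass
class RowErrorReport:
    """Rows rejected during reading, with 1-based data row numbers."""

    table: str
    errors: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row: int, reason: str) -> None:
        self.errors.append((row, reason))

    @property
    def n(self) -> int:
        return len(self.errors)


def read_table(
    path: str | Path,
    schema: str,
    max_malformed_fraction: float = 0.05,
) -> tuple[pd.DataFrame, RowErrorReport]:
    """Read and validate one TSV table.

    Malformed rows (bad integer, rating outside 1-7, empty key field) are
    dropped and collected in the returned report; more than
    ``max_malformed_fraction`` malformed rows raises :class:`SchemaError`.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    cols = SCHEMAS[schema]
    # utf-8-sig strips a BOM if present; pandas handles CRLF natively
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8-sig")
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")

    report = RowErrorReport(table=str(path))
    keep = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        ok = True
        for col, typ in cols.items():
            val = rec[col]
            if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
                report.add(i, f"empty {col}")
                ok = False
                break
            if typ is int:
                try:
                    rec[col] = int(val)
                except (TypeError, ValueError):
                    report.add(i, f"non-integer {col}: {val!r}")
                    ok = False
                    break
        if ok and schema == "ratings" and not (1 <= rec["rating"] <= 7):
            report.add(i, f"rating out of range: {rec['rating']}")
            ok = False
        if ok and schema in ("associates", "assignments") and rec["slot"] not in (1, 2):
            report.add(i, f"slot not in {{1,2}}: {rec['slot']}")
            ok = False
        if ok:
            keep.append(rec)
    if len(df) > 0 and report.n / len(df) > max_malformed_fraction:
        raise SchemaError(
            f"{path}: {report.n}/{len(df)} malformed rows exceeds "
            f"{max_malformed_fraction:.0%} cap"
        )
    out = pd.DataFrame(keep, columns=list(df.columns))
    for col, typ in cols.items():
        if typ is int and len(out):
            out[col] = out[col].astype(int)
    return out, report


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def write_zeugma_jsonl(items: Iterable[ZeugmaItem], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for it in items:
            fh.write(json.dumps(dataclasses.asdict(it), ensure_ascii=False) + "\n")


def read_zeugma_jsonl(path: str | Path) -> list[ZeugmaItem]:
    items = []
    with Path(path).open("r", encoding="utf-8-sig") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            rec["target_span"] = tuple(rec["target_span"])
            rec["anaphor_span"] = tuple(rec["anaphor_span"])
            items.append(ZeugmaItem(**rec))
    return items


# ---------------------------------------------------------------------------
# pipeline runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Parameters of one end-to-end synthetic pipeline run."""

    seed: int = 0
    out_dir: str = "runs"
    n_words: int = 12
    n_norming_participants: int = 60
    n_rating_participants: int = 40
    n_flat_raters: int = 2
    items_per_condition: int = 20
    dominance_cutoff: float = 0.75
    flat_threshold: float = 0.5
    log_base: str = "e"
    alpha: float = 0.01
    encoder: str = "toy"
    encoder_layers: int = 6
    encoder_dim: int = 48
    multiword_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.dominance_cutoff <= 1.0):
            raise ValueError("dominance_cutoff outside (0, 1]")
        if self.flat_threshold < 0:
            raise ValueError("flat_threshold must be >= 0")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha outside (0, 1)")
        if self.encoder != "toy":
            raise ValueError(
                f"unknown encoder {self.encoder!r}; only the deterministic "
                "'toy' encoder is available"
            )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Run simulate -> dominance -> similarity -> encoder metrics -> LRTs.

    Writes every intermediate table plus a JSON manifest (seed, config
    hash, package version, exclusion counts) into an output directory named
    by the config hash, so re-running an identical config reproduces the
    same directory byte-for-byte.  Returns the run directory.
    """
    from ambignorm import dominance as dom
    from ambignorm import inference, nlm_metrics, similarity, synthetic_data as syn

    run_dir = Path(config.out_dir) / f"run-{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "encoder": {"name": config.encoder, "n_layers": config.encoder_layers,
                    "dim": config.encoder_dim, "log_base": config.log_base},
        "stages": {},
    }

    try:
        # --- associate norming and dominance -----------------------------
        assoc_cfg = syn.AssociateStudyConfig(
            n_words=config.n_words,
            n_participants=config.n_norming_participants,
            true_sense_probs=(0.6, 0.4),
            seed=config.seed,
        )
        study = syn.simulate_associate_study(assoc_cfg)
        write_table(study.responses, run_dir / "associates.tsv")
        write_table(study.assignments, run_dir / "assignments.tsv")
        table, skipped = dom.dominance_table(
            study.assignments,
            {w: 2 for w in study.responses["word"].unique()},
            cutoff=config.dominance_cutoff,
        )
        write_table(table, run_dir / "dominance.tsv")
        coverage, consistency = dom.interrater_reliability(study.assignments)
        manifest["stages"]["dominance"] = {
            "n_words": int(len(table)),
            "skipped_words": skipped,
            "rater_coverage": coverage,
            "rater_consistency": consistency,
        }

        # --- zeugma items, ratings, similarity ---------------------------
        items = syn.generate_zeugma_items(
            config.items_per_condition,
            seed=config.seed,
            multiword_fraction=config.multiword_fraction,
        )
        write_zeugma_jsonl(items, run_dir / "zeugma.jsonl")
        rating = syn.simulate_ratings_for_zeugma_items(
            items,
            n_participants=config.n_rating_participants,
            n_flat_raters=config.n_flat_raters,
            seed=config.seed,
        )
        write_table(rating.ratings, run_dir / "ratings.tsv")
        write_table(rating.items, run_dir / "items.tsv")

        conds = rating.items.set_index("item")["condition"]
        report = similarity.exclude_participants(
            rating.ratings, conds, flat_threshold=config.flat_threshold
        )
        kept_ratings = rating.ratings[
            rating.ratings["participant_id"].isin(report.kept)
        ]
        stats_df = similarity.item_statistics(kept_ratings, conds)
        write_table(stats_df, run_dir / "item_stats.tsv")
        summary = similarity.condition_statistics(stats_df, alpha=config.alpha)
        agreement = similarity.loo_agreement(kept_ratings)
        manifest["stages"]["similarity"] = {
            "n_kept_participants": len(report.kept),
            "excluded": report.excluded.to_dict(orient="records"),
            "condition_stats": summary.stats.to_dict(orient="records"),
            "pairwise_tests": [dataclasses.asdict(t) for t in summary.tests],
            "loo_agreement": {
                "mean": agreement.mean, "sd": agreement.sd,
                "median": agreement.median,
                "min": agreement.min, "max": agreement.max,
            },
        }

        # --- encoder metrics ---------------------------------------------
        retained, removed = nlm_metrics.filter_multiword_anaphors(items)
        encoder = syn.make_toy_encoder(
            syn.ToyEncoderConfig(
                n_layers=config.encoder_layers,
                dim=config.encoder_dim,
                seed=config.seed,
            ),
            retained,
        )
        metrics = nlm_metrics.compute_item_metrics(
            encoder, retained, base=config.log_base
        )
        write_table(metrics, run_dir / "nlm_metrics.tsv")
        item_means = stats_df.set_index("item")["mean"]
        sweep = nlm_metrics.layer_correlations(metrics, item_means)
        write_table(sweep.to_frame(), run_dir / "layer_correlations.tsv")
        manifest["stages"]["nlm"] = {
            "n_multiword_removed": len(removed),
            "n_items": len(retained),
            "strongest_layer": sweep.strongest_layer,
        }

        # --- nested model comparisons ------------------------------------
        final = metrics[metrics["layer"] == config.encoder_layers]
        anaphors = {it.item: it.anaphor_text for it in retained}
        merged = (
            final.set_index("item")[["condition", "d_cos", "surprisal"]]
            .rename(columns={"d_cos": "cosine_distance"})
            .join(item_means.rename("mean_similarity"), how="inner")
            .reset_index()
        )
        merged["anaphor"] = merged["item"].map(anaphors)
        comparisons = inference.compare_metrics(merged)
        manifest["stages"]["inference"] = [
            {
                "full": c.full.formula,
                "reduced": c.reduced.formula,
                "chi2": c.chi2,
                "df": c.df,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
            }
            for c in comparisons
        ]
    except Exception as err:
        (run_dir / "FAILED.json").write_text(
            json.dumps({"error": repr(err)}, indent=2) + "\n"
        )
        raise
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return run_dir
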