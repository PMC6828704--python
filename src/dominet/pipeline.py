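"""End-to-end analysis: ingest -> tally -> per-day hierarchies -> networks -> QAP.

One call to :func:`run_pipeline` reproduces the whole analysis from the three
input files (interaction table, session table, ethogram) under a single
global seed, and writes a machine-readable JSON report plus a human-readable
text summary and CSV tables. Every number in the report is regenerable from
the config, the inputs and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dominance import (
    DavidsScores,
    EloConfig,
    EloResult,
    compare_rankings,
    davids_scores,
    pooled_rank_comparison,
    randomized_elo,
)
from .interactions import build_win_loss_matrix, read_interactions, tally_interactions
from .networks import build_network, consistency_report

__all__ = ["AnalysisConfig", "AnalysisReport", "run_pipeline"]

log = logging.getLogger("dominet")

# named substreams fanned out from the global seed
_STREAM_ELO = 1
_STREAM_QAP = 2
_STREAM_SIMULATE = 3


def derive_seed(global_seed: int, stream: int, index: int = 0) -> int:
    """Deterministic per-stage seed below 2**31."""
    state = np.random.SeedSequence([global_seed, stream, index]).generate_state(1)[0]
    return int(state >> 1)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to reproduce one full analysis run."""

    interactions_path: str
    sessions_path: str
    ethogram_path: str
    elo: EloConfig = EloConfig()
    qap_n_permutations: int = 1000
    qap_mode: str = "sampled"
    qap_all_pairs: bool = False
    seed: int = 0
    output_dir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        elo = EloConfig(**data.pop("elo", {}))
        return cls(elo=elo, **data)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Structured output of one pipeline run."""

    tally: pd.DataFrame
    per_day: dict[str, dict[str, Any]]  # session_id -> {elo, davids, comparison}
    pooled_comparison: Any
    networks: dict[str, list]  # type -> [InteractionNetwork, ...]
    qap: dict[str, Any]  # type -> ConsistencyReport
    skipped_days: list[tuple[str, str]]
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        def round6(x: float) -> float | None:
            return None if pd.isna(x) else round(float(x), 6)

        out: dict[str, Any] = {
            "provenance": self.provenance,
            "tally": {
                str(k): {c: round6(v) for c, v in row.items()}
                for k, row in self.tally.iterrows()
            },
            "per_day": {},
            "skipped_days": [list(s) for s in self.skipped_days],
            "qap": {},
        }
        for sid, stage in self.per_day.items():
            elo: EloResult = stage["elo"]
            ds: DavidsScores = stage["davids"]
            cmp_ = stage["comparison"]
            out["per_day"][sid] = {
                "elo_mean_scores": {i: round6(v) for i, v in elo.mean_scores.items()},
                "elo_ranking": elo.ranking,
                "elo_ties": [list(t) for t in elo.ties],
                "davids_DS": {i: round6(v) for i, v in ds.DS.items()},
                "davids_normDS": {i: round6(v) for i, v in ds.normDS.items()},
                "davids_ranking": ds.ranking,
                "comparison": {
                    "n": cmp_.n,
                    "pearson_r": round6(cmp_.pearson_r),
                    "pearson_p": round6(cmp_.pearson_p),
                    "spearman_rho": round6(cmp_.spearman_rho),
                    "spearman_p": round6(cmp_.spearman_p),
                },
            }
        pc = self.pooled_comparison
        out["pooled_comparison"] = None if pc is None else {
            "n": pc.n,
            "pearson_r": round6(pc.pearson_r),
            "pearson_p": round6(pc.pearson_p),
            "spearman_rho": round6(pc.spearman_rho),
            "spearman_p": round6(pc.spearman_p),
        }
        for net_type, rep in self.qap.items():
            out["qap"][net_type] = {
                "pairs": [
                    {k: (round6(v) if isinstance(v, float) else v) for k, v in row.items()}
                    for row in rep.table.to_dict(orient="records")
                ],
                "skipped": [list(s) for s in rep.skipped],
            }
        out["networks"] = {
            net_type: [
                {
                    "session_id": net.session_id,
                    "individuals": net.individuals,
                    "duration_hours": net.duration_hours,
                    "total_interactions": int(net.raw_counts.sum()),
                }
                for net in nets
            ]
            for net_type, nets in self.networks.items()
        }
        return out

    def to_text(self) -> str:
        lines = [f"dominet analysis report (v{self.provenance.get('version', '?')})"]
        lines.append(f"config hash: {self.provenance.get('config_hash')}"
                     f"  seed: {self.provenance.get('seed')}")
        lines.append("")
        lines.append("Interaction tally (rows: sessions + total/mean/sd):")
        lines.append(self.tally.to_string(float_format=lambda v: f"{v:.1f}"))
        lines.append("")
        for sid, stage in self.per_day.items():
            elo = stage["elo"]
            cmp_ = stage["comparison"]
            lines.append(
                f"{sid}: Elo ranking {' > '.join(elo.ranking)}"
                f"  (Elo~DS Spearman {cmp_.spearman_rho:.3f})"
            )
        if self.skipped_days:
            for sid, reason in self.skipped_days:
                lines.append(f"{sid}: skipped ({reason})")
        pc = self.pooled_comparison
        if pc is not None:
            lines.append(
                f"pooled Elo vs David's score: r = {pc.pearson_r:.3f}"
                f" (p = {pc.pearson_p:.3g}, n = {pc.n})"
            )
        lines.append("")
        for net_type, rep in self.qap.items():
            lines.append(f"QAP consistency ({net_type} networks):")
            if rep.table.empty:
                lines.append("  no comparable same-roster pairs")
            else:
                lines.append(rep.table.to_string(index=False,
                                                 float_format=lambda v: f"{v:.3f}"))
            for a, b, reason in rep.skipped:
                lines.append(f"  {a} vs {b}: skipped ({reason})")
        return "\n".join(lines) + "\n"


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Run the full analysis described by ``config``.

    Stages: read and validate the inputs; tally interactions by category;
    per observation day, infer the hierarchy by randomized Elo and by David's
    scores (on decided agonistic interactions of present individuals) and
    compare them; build rate-normalised agonistic and affiliative networks
    ordered by the day's Elo ranking; run QAP consistency tests between
    same-roster consecutive sessions. Days without decided agonistic
    interactions are skipped and listed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    records, sessions = read_interactions(
        config.interactions_path, config.sessions_path, config.ethogram_path
    )
    n_ambiguous = sum(r.category == "ambiguous" for r in records)
    n_draws = sum(r.outcome == "draw" for r in records)
    log.info(
        "read %d records over %d sessions (%d ambiguous excluded downstream, "
        "%d agonistic draws excluded from hierarchies)",
        len(records), len(sessions), n_ambiguous, n_draws,
    )
    tally = tally_interactions(records, sessions)

    per_day: dict[str, dict[str, Any]] = {}
    skipped_days: list[tuple[str, str]] = []
    pooled_pairs = []
    rankings: dict[str, list[str]] = {}
    for s_idx, session in enumerate(sessions):
        present = sorted(session.individuals_present)
        decided = [
            r for r in records
            if r.session_id == session.session_id
            and r.category == "agonistic" and r.decided
        ]
        if not decided:
            skipped_days.append((session.session_id, "no decided agonistic interactions"))
            log.info("session %s: skipped (no decided agonistic interactions)",
                     session.session_id)
            continue
        elo_cfg = replace(config.elo, rng_seed=derive_seed(config.seed, _STREAM_ELO, s_idx))
        elo = randomized_elo(decided, present, elo_cfg)
        ds = davids_scores(build_win_loss_matrix(decided, present))
        per_day[session.session_id] = {
            "elo": elo,
            "davids": ds,
            "comparison": compare_rankings(elo, ds),
        }
        pooled_pairs.append((elo, ds))
        rankings[session.session_id] = elo.ranking
        log.info("session %s: %d decided contests, Elo ranking %s",
                 session.session_id, len(decided), " > ".join(elo.ranking))

    pooled = pooled_rank_comparison(pooled_pairs) if len(pooled_pairs) >= 1 else None

    networks: dict[str, list] = {"agonistic": [], "affiliative": []}
    for session in sessions:
        ranking = rankings.get(session.session_id, sorted(session.individuals_present))
        for net_type in ("agonistic", "affiliative"):
            networks[net_type].append(
                build_network(records, session, net_type, ranking)
            )
    qap: dict[str, Any] = {}
    for t_idx, net_type in enumerate(("agonistic", "affiliative")):
        qap[net_type] = consistency_report(
            networks[net_type],
            n_permutations=config.qap_n_permutations,
            seed=derive_seed(config.seed, _STREAM_QAP, t_idx),
            mode=config.qap_mode,
            all_pairs=config.qap_all_pairs,
        )

    report = AnalysisReport(
        tally=tally,
        per_day=per_day,
        pooled_comparison=pooled,
        networks=networks,
        qap=qap,
        skipped_days=skipped_days,
        provenance={
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.content_hash(),
        },
    )
    if config.output_dir is not None:
        _write_outputs(report, Path(config.output_dir))
    return report


def _write_outputs(report: AnalysisReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out_dir / "report.txt").write_text(report.to_text(), encoding="utf-8")
    report.tally.to_csv(out_dir / "tally.csv")
    score_rows = []
    for sid, stage in report.per_day.items():
        elo, ds = stage["elo"], stage["davids"]
        for ind in elo.individuals:
            score_rows.append(
                {
                    "session_id": sid,
                    "individual": ind,
                    "mean_elo": elo.mean_scores[ind],
                    "DS": ds.DS[ind],
                    "normDS": ds.normDS[ind],
                    "elo_rank": elo.ranking.index(ind) + 1,
                    "davids_rank": ds.ranking.index(ind) + 1,
                }
            )
    pd.DataFrame(score_rows).to_csv(out_dir / "scores_per_day.csv", index=False)
    for net_type, rep in report.qap.items():
        rep.table.to_csv(out_dir / f"qap_{net_type}.csv", index=False)
    for net_type, nets in report.networks.items():
        for net in nets:
            net.to_frame(rates=True).to_csv(
                out_dir / f"network_{net_type}_{net.session_id}.csv"
            )
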