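"""End-to-end pipeline: one cohort table in, a reproducible report bundle out.

A run reads and validates the cohort, binarizes it, and writes:

* ``summary.tsv``   — per-molecule prevalence summaries (all/child/adult);
* ``profiles.tsv``  — ranked exact-set sensitization profiles per group;
* ``regions.tsv``   — priority-molecule decisions per region (and per
  region x age group), exclusions included;
* ``regions_trace.tsv`` — the full per-molecule p-value map behind each
  t-step decision;
* ``manifest.json`` — resolved configuration, input checksum, row counts
  and tool version.

Every parameter flows from one resolved :class:`RunConfig`; nothing is
hard-coded in the stages, so the conventional defaults (0.35 kU/L
threshold, 5-point margin, 5% p-similarity, 0.002 annotation level,
minimum group size 3) are defaults, not constants. Identical input and
configuration produce byte-identical outputs. On any stage error the
partial outputs of this run are removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .panel_io import DEFAULT_PANEL, read_cohort, write_table
from .profiles import enumerate_profiles
from .regional import PriorityConfig, classify_all_regions
from .sensitization import BinarizationConfig, binarize
from .summary import summarize, total_sensitized

logger = logging.getLogger("hdmprof")

GROUPS = ("all", "child", "adult")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    input_path: str
    output_dir: str
    threshold: float = 0.35
    margin: float = 0.05
    p_similarity: float = 0.05
    alpha: float = 0.002
    min_group_n: int = 3
    dialect: str = "tab"
    panel: tuple[str, ...] = DEFAULT_PANEL
    groups: tuple[str, ...] = GROUPS
    top_profiles: int = 0  # 0 = all
    float_precision: int = 4

    def priority_config(self) -> PriorityConfig:
        return PriorityConfig(
            margin=self.margin,
            p_similarity=self.p_similarity,
            alpha=self.alpha,
            min_group_n=self.min_group_n,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _summary_rows(cohort, matrix, groups):
    for group in groups:
        for r in summarize(cohort, matrix, group):
            yield {
                "group": r.group,
                "molecule": r.molecule,
                "n_sensitized": r.n_sensitized,
                "share_pct": r.share_pct,
                "mean_sige": r.mean_sige,
                "sd_sige": r.sd_sige,
            }


def _profile_rows(cohort, matrix, groups, top):
    for group in groups:
        table = enumerate_profiles(cohort, matrix, group)
        chosen = table.profiles if top <= 0 else table.profiles[:top]
        for rank, p in enumerate(chosen, start=1):
            yield {
                "group": group,
                "rank": rank,
                "profile_label": p.label,
                "n_molecules": len(p.members),
                "n": p.count,
                "share_pct": p.share_pct,
            }


def _region_rows(decisions):
    for d in decisions:
        t = d.trace
        yield {
            "region": d.region,
            "group": d.group,
            "priority_1": d.priority[0] if d.priority else "",
            "priority_2": d.priority[1] if len(d.priority) > 1 else "",
            "share_1": t.first_max[1] if t.first_max else math.nan,
            "share_2": t.second_max[1] if t.second_max else math.nan,
            "rule_path": t.rule_path or "",
            "excluded_reason": d.excluded_reason,
        }


def _trace_rows(decisions):
    for d in decisions:
        for molecule, p in d.trace.p_values.items():
            yield {
                "region": d.region,
                "group": d.group,
                "molecule": molecule,
                "p_value": p,
                "unconfirmed_at_alpha": d.trace.unconfirmed_at_alpha.get(molecule, True),
            }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Any stage error removes the partial outputs of this run and re-raises.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, rows) -> int:
        path = outdir / name
        rows = list(rows)
        write_table(rows, path, dialect=config.dialect, float_precision=config.float_precision)
        written.append(path)
        return len(rows)

    try:
        in_path = Path(config.input_path)
        cohort = read_cohort(in_path, panel=config.panel, dialect=config.dialect)
        matrix = binarize(cohort, BinarizationConfig(config.threshold))
        logger.info("read %d patients, %d regions", len(cohort), len(cohort.region_set))

        counts = {"summary.tsv": emit("summary.tsv", _summary_rows(cohort, matrix, config.groups))}
        counts["profiles.tsv"] = emit(
            "profiles.tsv", _profile_rows(cohort, matrix, config.groups, config.top_profiles)
        )
        decisions = classify_all_regions(cohort, matrix, config.priority_config(), by="all")
        decisions += classify_all_regions(cohort, matrix, config.priority_config(), by="age")
        for d in decisions:
            if d.excluded:
                logger.info("region %s/%s excluded: %s", d.region, d.group, d.excluded_reason)
        counts["regions.tsv"] = emit("regions.tsv", _region_rows(decisions))
        counts["regions_trace.tsv"] = emit("regions_trace.tsv", _trace_rows(decisions))

        manifest = {
            "tool": "hdmprof",
            "version": __version__,
            # output_dir is omitted: it is where the manifest itself lives,
            # and recording it would break byte-identity across output dirs
            "config": {
                **{k: v for k, v in asdict(config).items() if k != "output_dir"},
                "panel": list(config.panel),
                "groups": list(config.groups),
            },
            "input_sha256": _sha256(in_path),
            "n_patients": len(cohort),
            "n_regions": len(cohort.region_set),
            "n_sensitized": total_sensitized(cohort, matrix, "all"),
            "table_rows": counts,
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
        return manifest
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
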