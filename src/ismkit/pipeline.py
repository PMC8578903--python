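"""End-to-end pipeline orchestration.

Runs ratification → aggregation (or direct SSIM/matrix input) → initial
reachability matrix → transitive closure → powers → level partitioning →
conical matrix → digraph → MICMAC → summary, writing every intermediate
artifact to the output directory and logging each stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as ismio
from .datasets import load_case_study
from .engine import (
    ClosureAudit,
    ConicalMatrix,
    LevelPartition,
    PowerVector,
    ReachabilityMatrix,
    StructuralDigraph,
    audit_closure_consistency,
    build_conical_matrix,
    build_digraph,
    compute_powers,
    partition_levels,
    ssim_to_initial_rm,
    transitive_closure,
)
from .errors import ValidationError
from .micmac import MicmacConfig, MicmacResult, classify_factors, summarize
from .report import (
    audit_markdown,
    conical_markdown,
    iterations_markdown,
    matrix_markdown,
    ssim_markdown,
    summary_markdown,
)
from .roster import DeterminantRoster, RatificationResult, aggregate_judgments, ratify_determinants
from .ssim import SSIM

log = logging.getLogger("ismkit")

CLOSURE_MODES = ("as_given", "one_pass", "full")


@dataclass
class PipelineConfig:
    """Plain-text-serializable run configuration.

    Exactly one of the SSIM sources should be provided: a judgments file
    (aggregated by majority), an SSIM file, or the packaged case study.
    An as-given final matrix may accompany either; with
    ``closure_mode='as_given'`` it is used verbatim for the downstream
    stages, otherwise the chosen closure of the initial matrix is used.
    """

    out_dir: str = "ism_out"
    closure_mode: str = "as_given"
    boundary: float | None = None  # MICMAC boundary; default n/2
    ratify_tie_policy: str = "include"
    aggregate_tie_policy: str = "priority_order"
    roster_path: str | None = None
    votes_path: str | None = None
    judgments_path: str | None = None
    ssim_path: str | None = None
    matrix_path: str | None = None  # as-given final matrix
    case_study: bool = False
    audit: bool = True
    report: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.closure_mode not in CLOSURE_MODES:
            raise ValidationError(
                f"closure_mode must be one of {CLOSURE_MODES}, got {self.closure_mode!r}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class RunArtifacts:
    """Everything one pipeline run produced."""

    config: PipelineConfig
    roster: DeterminantRoster
    ratification: RatificationResult | None
    ssim: SSIM | None
    initial_rm: ReachabilityMatrix | None
    final_rm: ReachabilityMatrix
    powers: PowerVector
    partition: LevelPartition
    conical: ConicalMatrix
    digraph: StructuralDigraph
    micmac: MicmacResult
    summary: pd.DataFrame
    audit: ClosureAudit | None


def run_pipeline(config: PipelineConfig) -> RunArtifacts:
    """Execute every stage of the configured run and write its artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    roster = None
    votes = None
    ssim: SSIM | None = None
    as_given: ReachabilityMatrix | None = None

    if config.case_study:
        study = load_case_study()
        roster, votes, ssim, as_given = (
            study.roster,
            list(study.votes),
            study.ssim,
            study.final_rm,
        )
    if config.roster_path:
        roster = ismio.read_roster(config.roster_path)
    if roster is None:
        raise ValidationError("no roster: set roster_path or case_study")
    if config.votes_path:
        votes = ismio.read_votes(config.votes_path)

    ratification = None
    if votes:
        ratification = ratify_determinants(votes, tie_policy=config.ratify_tie_policy)
        log.info(
            "stage ratify: %d/%d factors included (%d ties)",
            len(ratification.included_codes),
            len(votes),
            len(ratification.tie_flags),
        )

    if config.judgments_path:
        panel = ismio.read_judgments(config.judgments_path)
        ssim, tallies = aggregate_judgments(
            panel, roster.codes, tie_policy=config.aggregate_tie_policy
        )
        log.info(
            "stage aggregate: %d experts, %d pairs, %d tied pairs",
            len(panel),
            len(tallies),
            sum(1 for t in tallies if t.majority_kind == "tie"),
        )
    elif config.ssim_path:
        ssim = ismio.read_ssim(config.ssim_path)
    if config.matrix_path:
        as_given = ismio.read_matrix(config.matrix_path, flavor="as_given")

    initial = ssim_to_initial_rm(ssim) if ssim is not None else None
    if initial is not None:
        log.info("stage initial_rm: %d factors, %d direct cells", initial.n, int(initial.binary.sum()))

    if config.closure_mode == "as_given":
        if as_given is None:
            raise ValidationError(
                "closure_mode='as_given' requires an as-given final matrix "
                "(matrix_path or the case study)"
            )
        final = as_given
    else:
        base = initial if initial is not None else as_given
        if base is None:
            raise ValidationError("no SSIM or matrix input available")
        final = transitive_closure(base, mode=config.closure_mode)
    log.info("stage closure[%s]: %d cells set", final.flavor, int(final.binary.sum()))

    powers = compute_powers(final)
    partition = partition_levels(final)
    log.info("stage levels: %d levels %s", partition.depth, [list(l) for l in partition.levels])
    conical = build_conical_matrix(final, partition)
    # the model digraph is drawn from the direct relation when one is
    # available; closure cells would collapse distinct levels into one SCC
    digraph = build_digraph(initial if initial is not None else final, partition)
    micmac = classify_factors(
        powers, MicmacConfig(n=final.n, boundary=config.boundary)
    )
    summary = summarize(roster, partition, micmac)

    audit = None
    if config.audit and as_given is not None and initial is not None:
        audit = audit_closure_consistency(as_given, initial)
        log.info(
            "stage audit: %s",
            "consistent" if audit.consistent else "discrepancies found",
        )

    artifacts = RunArtifacts(
        config=config,
        roster=roster,
        ratification=ratification,
        ssim=ssim,
        initial_rm=initial,
        final_rm=final,
        powers=powers,
        partition=partition,
        conical=conical,
        digraph=digraph,
        micmac=micmac,
        summary=summary,
        audit=audit,
    )
    _write_artifacts(artifacts, out)
    return artifacts


def _write_artifacts(a: RunArtifacts, out: Path) -> None:
    ismio.write_roster(a.roster, out / "roster.csv")
    if a.ssim is not None:
        ismio.write_ssim(a.ssim, out / "ssim.csv")
    if a.initial_rm is not None:
        ismio.write_matrix(a.initial_rm, out / "reachability_initial.csv")
    ismio.write_matrix(a.final_rm, out / "reachability_final.csv")
    ismio.write_matrix(
        ReachabilityMatrix(a.conical.order, a.conical.cells, flavor=a.final_rm.flavor),
        out / "conical.csv",
    )
    ismio.write_dot(a.digraph, out / "model.dot")
    a.summary.to_csv(out / "summary.csv", index=False)
    with open(out / "levels.json", "w", encoding="utf-8") as fh:
        json.dump(
            {k: list(v) for k, v in a.partition.as_dict().items()}, fh, indent=2
        )
    if a.config.report:
        (out / "report.md").write_text(render_report(a), encoding="utf-8")
    log.info("artifacts written to %s", out)


def render_report(a: RunArtifacts) -> str:
    """Render all run artifacts as one markdown report (pure function)."""
    parts = ["# ISM / MICMAC analysis report", ""]
    if a.ratification is not None:
        rows = [
            [
                str(code),
                str(a.ratification.tallies[code][0]),
                str(a.ratification.tallies[code][1]),
                "included" if code in a.ratification.included_codes else "excluded",
                "tie" if code in a.ratification.tie_flags else "",
            ]
            for code in sorted(a.ratification.tallies)
        ]
        header = "| Code | Yes | No | Decision | Note |\n|---|---|---|---|---|\n"
        body = "\n".join("| " + " | ".join(r) + " |" for r in rows)
        parts += ["## Ratification\n", header + body, ""]
    if a.ssim is not None:
        parts += ["## Structural self-interaction matrix\n", ssim_markdown(a.ssim), ""]
    if a.initial_rm is not None:
        parts += [
            "## Initial reachability matrix\n",
            matrix_markdown(a.initial_rm, margins=False),
            "",
        ]
    parts += [
        f"## Final reachability matrix ({a.final_rm.flavor})\n",
        matrix_markdown(a.final_rm),
        "",
        "## Level partitioning\n",
        iterations_markdown(a.partition),
        "",
        "### Model levels\n",
        "\n".join(
            f"- Level {roman} = {{{', '.join(map(str, codes))}}}"
            for roman, codes in a.partition.as_dict().items()
        ),
        "",
        "## Conical matrix\n",
        conical_markdown(a.conical),
        "",
        "## Summarized and juxtaposed results\n",
        summary_markdown(a.summary),
        "",
    ]
    if a.audit is not None:
        parts += ["## Discrepancy ledger\n", audit_markdown(a.audit), ""]
    return "\n".join(parts)
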