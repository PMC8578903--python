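"""Packaged case-study dataset.

Ships the complete elicitation record of a published desk-scale ISM +
MICMAC study of the determinants of COVID-19 SOP effectiveness in mass
gatherings: an 11-factor roster, the 10-expert ratification votes, the
aggregated SSIM, the initial reachability matrix, the final (as-given)
reachability matrix with transitive ``1*`` marks, the published level
partition with the first-iteration set triples, and the published
juxtaposed summary table.

All artifacts are stored bit-exact as transcribed. The final matrix is
deliberately loaded ``as_given``: it is *not* the full transitive closure
of the initial matrix (see :func:`ismkit.engine.audit_closure_consistency`),
and the loaders never repair published data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .engine import ReachabilityMatrix, ssim_to_initial_rm
from .io import read_matrix, read_roster, read_ssim, read_votes
from .roster import DeterminantRoster, VoteSheet
from .ssim import SSIM

_DATA = "sop_mass_gathering"


def _path(name: str):
    return resources.files("ismkit").joinpath("datasets", _DATA, name)


@dataclass(frozen=True)
class CaseStudy:
    """Bundle of every artifact of the packaged study, mutually validated."""

    roster: DeterminantRoster
    votes: tuple[VoteSheet, ...]
    ssim: SSIM
    initial_rm: ReachabilityMatrix
    final_rm: ReachabilityMatrix  # as_given, with transitive marks
    published_levels: dict[str, tuple[int, ...]]  # Roman numeral -> codes
    published_iteration_1: dict[int, dict]  # code -> set triple + leveled flag
    published_summary: pd.DataFrame


def load_case_study(validate: bool = True) -> CaseStudy:
    """Load the packaged study; by default cross-check SSIM ↔ initial matrix."""
    with resources.as_file(_path("roster.csv")) as p:
        roster = read_roster(p)
    with resources.as_file(_path("votes.csv")) as p:
        votes = tuple(read_votes(p))
    with resources.as_file(_path("ssim.csv")) as p:
        ssim = read_ssim(p)
    with resources.as_file(_path("reachability_initial.csv")) as p:
        initial = read_matrix(p, flavor="initial")
    with resources.as_file(_path("reachability_final.csv")) as p:
        final = read_matrix(p, flavor="as_given")
    payload = json.loads(_path("published_levels.json").read_text(encoding="utf-8"))
    levels = {k: tuple(v) for k, v in payload["levels"].items()}
    iter1 = {
        int(code): {
            "reachability": frozenset(rec["reachability"]),
            "antecedent": frozenset(rec["antecedent"]),
            "intersection": frozenset(rec["intersection"]),
            "leveled": bool(rec["leveled"]),
        }
        for code, rec in payload["iteration_1"].items()
    }
    with resources.as_file(_path("summary.csv")) as p:
        summary = pd.read_csv(p, keep_default_na=False)

    if validate:
        decoded = ssim_to_initial_rm(ssim)
        if decoded.codes != initial.codes or not np.array_equal(
            decoded.binary, initial.binary
        ):
            raise AssertionError(
                "packaged SSIM and initial reachability matrix are inconsistent"
            )
    return CaseStudy(
        roster=roster,
        votes=votes,
        ssim=ssim,
        initial_rm=initial,
        final_rm=final,
        published_levels=levels,
        published_iteration_1=iter1,
        published_summary=summary,
    )
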