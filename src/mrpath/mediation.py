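"""Stage 4 — two-step MR mediation with the Sobel indirect-effect test.

The indirect (mediated) effect of an exposure on an outcome through a
mediator is the product a*b of the exposure->mediator causal estimate a and
the mediator->outcome causal estimate b.  The classic (first-order) Sobel
standard error is

    se_ab = sqrt(a^2 se_b^2 + b^2 se_a^2)

with z = a*b / se_ab referred to a two-sided standard normal.  The
second-order variant (adding se_a^2 se_b^2) is available behind a flag.
Direct effects are deliberately not estimated; only indirect effects are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import AnalysisError
from .mr import MRResult

__all__ = ["MediationResult", "sobel", "two_step_mediation", "mediation_network"]


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    a: float
    se_a: float
    b: float
    se_b: float
    indirect: float
    se_indirect: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    degenerate: bool = False
    n_instruments_step1: int | None = None
    n_instruments_step2: int | None = None

    def as_dict(self):
        return dict(self.__dict__)


def sobel(
    a: float, se_a: float, b: float, se_b: float,
    labels: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
    second_order: bool = False,
) -> MediationResult:
    """Sobel test of the indirect effect a*b.

    Symmetric in its (a, se_a) / (b, se_b) arguments.  The degenerate case
    a = b = 0 has an undefined z and returns indirect 0, p = 1 with the
    ``degenerate`` flag set.
    """
    if not (se_a > 0 and se_b > 0):
        raise AnalysisError("sobel requires positive standard errors")
    indirect = a * b
    var = a * a * se_b * se_b + b * b * se_a * se_a
    if second_order:
        var += se_a * se_a * se_b * se_b
    se = float(np.sqrt(var))
    if se == 0.0:
        return MediationResult(
            *labels, a=a, se_a=se_a, b=b, se_b=se_b,
            indirect=0.0, se_indirect=0.0, z=np.nan, p=1.0,
            ci_low=0.0, ci_high=0.0, degenerate=True,
        )
    z = indirect / se
    p = max(2.0 * norm.sf(abs(z)), np.finfo(float).tiny) if indirect != 0.0 else 1.0
    return MediationResult(
        *labels, a=a, se_a=se_a, b=b, se_b=se_b,
        indirect=indirect, se_indirect=se, z=z, p=p,
        ci_low=indirect - 1.96 * se, ci_high=indirect + 1.96 * se,
    )


def two_step_mediation(
    step1: MRResult,
    step2: MRResult,
    labels: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
    second_order: bool = False,
) -> MediationResult:
    """Combine the exposure->mediator and mediator->outcome MR estimates.

    ``step1`` must be the causal estimate of the mediator on the exposure's
    instruments; ``step2`` the causal estimate of the outcome on the
    mediator's instruments (selected by the same instrument rules).
    """
    if step1 is None or step2 is None:
        raise AnalysisError("both mediation steps are required")
    result = sobel(step1.beta, step1.se, step2.beta, step2.se,
                   labels=labels, second_order=second_order)
    result.n_instruments_step1 = step1.n_instruments
    result.n_instruments_step2 = step2.n_instruments
    return result


def mediation_network(
    results: list[MediationResult],
    mr_edges: list[tuple[str, str, MRResult]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node/edge tables summarising mediators, outcomes and their MR edges.

    Every mediation result contributes its exposure -> mediator and
    mediator -> outcome direct edges (betas from the two MR steps) plus an
    indirect-effect annotation on the mediator -> outcome edge; extra MR
    edges can be supplied explicitly.  Serialisable as TSV or DOT.
    """
    nodes: dict[str, str] = {}
    edges = []
    for r in results:
        nodes.setdefault(r.exposure, "exposure")
        nodes.setdefault(r.mediator, "mediator")
        nodes.setdefault(r.outcome, "outcome")
        edges.append({
            "source": r.exposure, "target": r.mediator, "kind": "mr_step1",
            "beta": r.a, "se": r.se_a, "p": np.nan,
            "indirect": np.nan, "indirect_ci_low": np.nan,
            "indirect_ci_high": np.nan, "indirect_p": np.nan,
        })
        edges.append({
            "source": r.mediator, "target": r.outcome, "kind": "mr_step2",
            "beta": r.b, "se": r.se_b, "p": np.nan,
            "indirect": r.indirect, "indirect_ci_low": r.ci_low,
            "indirect_ci_high": r.ci_high, "indirect_p": r.p,
        })
    for source, target, mr in mr_edges or []:
        nodes.setdefault(source, "phenotype")
        nodes.setdefault(target, "phenotype")
        edges.append({
            "source": source, "target": target, "kind": mr.method,
            "beta": mr.beta, "se": mr.se, "p": mr.p,
            "indirect": np.nan, "indirect_ci_low": np.nan,
            "indirect_ci_high": np.nan, "indirect_p": np.nan,
        })
    node_df = pd.DataFrame(
        {"node": list(nodes), "role": list(nodes.values())}
    )
    edge_cols = ["source", "target", "kind", "beta", "se", "p",
                 "indirect", "indirect_ci_low", "indirect_ci_high", "indirect_p"]
    edge_df = pd.DataFrame(edges, columns=edge_cols)
    # collapse duplicate edges (two mediation results sharing a step)
    edge_df = edge_df.drop_duplicates(subset=["source", "target", "kind"])
    return node_df.reset_index(drop=True), edge_df.reset_index(drop=True)


def network_to_dot(nodes: pd.DataFrame, edges: pd.DataFrame) -> str:
    """Render the mediation network as a Graphviz DOT document."""
    colors = {"exposure": "lightblue", "mediator": "lightgoldenrod",
              "outcome": "lightpink", "phenotype": "lightgrey"}
    lines = ["digraph mediation {", "  rankdir=LR;"]
    for rec in nodes.itertuples(index=False):
        color = colors.get(rec.role, "white")
        lines.append(f'  "{rec.node}" [style=filled, fillcolor={color}];')
    for rec in edges.itertuples(index=False):
        label = f"b={rec.beta:.3g}"
        if np.isfinite(rec.indirect):
            label += (f"\\nindirect={rec.indirect:.3g} "
                      f"[{rec.indirect_ci_low:.3g}, {rec.indirect_ci_high:.3g}]")
        lines.append(f'  "{rec.source}" -> "{rec.target}" [label="{label}"];')
    lines.append("}")
    return "\n".join(lines)
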