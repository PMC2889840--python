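"""Model/Results interface over the stage-wise refinement machinery.

:class:`DynamicPPANModel` bundles the inputs (expression data, the rough
candidate network, stage windows, fitting mode); ``fit()`` runs the
constrained least-squares + AIC pruning over every stage and returns a
:class:`PPANResults` carrying the refined networks, the per-target fit
records, the stage summary table, and the downstream cross-talk analysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import crosstalk as _crosstalk
from .model import PROXY, FitResult, RefinedPPAN, profiles_dict, refine_all_stages
from .network import RoughPPAN, write_graphml, write_sif
from .timecourse import (
    DEFAULT_STAGE_BOUNDARIES_HOURS,
    ExpressionMatrix,
    StageWindow,
    build_stage_windows,
)


class DynamicPPANModel:
    """Stage-resolved dynamic association model over a candidate network.

    Parameters
    ----------
    expression : ExpressionMatrix
        Symbol-keyed expression profiles (protein tracks in full mode,
        mRNA standing in for protein in proxy mode).
    rough : RoughPPAN
        Candidate association network; each node's neighbourhood is its
        candidate interactor set.
    windows : list[StageWindow], optional
        Stage windows; defaults to the study's hour boundaries applied to
        the expression grid.
    mode : {"proxy", "full"}
    mrna : ExpressionMatrix, optional
        mRNA tracks, required in full mode.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        rough: RoughPPAN,
        windows: list[StageWindow] | None = None,
        mode: str = PROXY,
        mrna: ExpressionMatrix | None = None,
    ) -> None:
        self.expression = expression
        self.rough = rough
        self.windows = windows or build_stage_windows(
            expression.times, DEFAULT_STAGE_BOUNDARIES_HOURS
        )
        self.mode = mode
        self.mrna = mrna

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, rough: RoughPPAN, **kwargs
    ) -> "DynamicPPANModel":
        """Build from a symbols x times DataFrame (columns in minutes)."""
        return cls(ExpressionMatrix(frame.copy()), rough, **kwargs)

    def fit(self) -> "PPANResults":
        data = profiles_dict(self.expression)
        xdata = profiles_dict(self.mrna) if self.mrna is not None else None
        networks, fits, summary = refine_all_stages(
            self.rough, self.windows, data, self.mode, xdata
        )
        return PPANResults(self, networks, fits, summary)


class PPANResults:
    """Fitted stage networks plus fit diagnostics and downstream analyses."""

    def __init__(
        self,
        model: DynamicPPANModel,
        networks: list[RefinedPPAN],
        fits: list[FitResult],
        stage_summary: pd.DataFrame,
    ) -> None:
        self.model = model
        self.networks = networks
        self.fits = fits
        self.stage_summary = stage_summary

    def fits_frame(self) -> pd.DataFrame:
        """Long-form fit table: one row per retained interactor per target."""
        rows = []
        for fit in self.fits:
            if not fit.selected:
                rows.append(
                    {"target": fit.target, "stage": fit.stage, "interactor": "",
                     "coefficient": np.nan, "k_star": fit.k_star, "aic": fit.aic}
                )
            for q in fit.selected:
                rows.append(
                    {"target": fit.target, "stage": fit.stage, "interactor": q,
                     "coefficient": fit.coefficients[q], "k_star": fit.k_star,
                     "aic": fit.aic}
                )
        return pd.DataFrame(
            rows, columns=["target", "stage", "interactor", "coefficient",
                           "k_star", "aic"]
        )

    def ctrv(self, assignment: _crosstalk.PathwayAssignment) -> _crosstalk.CTRVTable:
        """Cross-talk ranking values over all fitted stage networks."""
        return _crosstalk.compute_ctrv(self.networks, assignment)

    def node_color_attributes(self) -> pd.DataFrame:
        """Signed log2 ratio of each stage's mean expression vs the first
        time point (positive: above the untreated baseline)."""
        frame = self.model.expression.frame
        baseline = frame.iloc[:, 0]
        rows = {}
        for window, net in zip(self.model.windows, self.networks):
            vals = frame.iloc[:, list(window.point_indices)].mean(axis=1) - baseline
            rows[net.label] = vals
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable account of the fit, statsmodels style."""
        lines = [
            "Dynamic protein-protein association network fit",
            "=" * 55,
            f"mode: {self.model.mode}    stages: {len(self.networks)}    "
            f"targets fitted: {len({f.target for f in self.fits})}",
            f"rough network: {len(self.model.rough.nodes)} nodes, "
            f"{self.model.rough.n_edges} candidate edges",
            "-" * 55,
            self.stage_summary.to_string(index=False),
        ]
        return "\n".join(lines)

    def export(self, outdir: str | Path) -> list[Path]:
        """Write per-stage SIF + GraphML, the fit TSV and the summary TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for net in self.networks:
            sif = outdir / f"refined_stage{net.stage}.sif"
            gml = outdir / f"refined_stage{net.stage}.graphml"
            write_sif(net.graph, sif)
            g = net.graph.copy()
            for *_, d in g.edges(data=True):
                d["stage"] = net.stage
            write_graphml(g, gml)
            written += [sif, gml]
        fits_path = outdir / "fits.tsv"
        self.fits_frame().to_csv(fits_path, sep="\t", index=False)
        summary_path = outdir / "stage_summary.tsv"
        self.stage_summary.to_csv(summary_path, sep="\t", index=False)
        return written + [fits_path, summary_path]
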