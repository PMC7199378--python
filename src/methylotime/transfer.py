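"""Transfer of a trained pseudo-time model to external methylomes.

External bisulfite datasets rarely cover every marker interval of a trained
model, so transfer proceeds in three steps: intersect the model's markers
with the intervals quantified in the external data, refit the penalized
model on the *training* data restricted to those common markers (penalty
re-chosen by seeded cross-validation), and predict the external samples from
the refit model.

Marker identity is exact: chromosome, start, end *and* context class must
match, which requires the external matrices to be built on the same window
grid (same chromosome sizes, window and step size) as the training matrices.
Because the same genomic interval carries distinct CpG and non-CpG
methylation levels, datasets are handled as a per-context-class mapping
``{"CpG": matrix, "nonCpG": matrix}``; a bare matrix is accepted and keyed
by its own context class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import GenomicInterval, MethylationMatrix
from .selection import ElasticNetConfig, PluripotencyModel, fit_elastic_net

ContextMatrices = Mapping[str, MethylationMatrix]


def _as_context_map(m: MethylationMatrix | ContextMatrices) -> dict[str, MethylationMatrix]:
    if isinstance(m, MethylationMatrix):
        return {m.context_class: m}
    return dict(m)


def _shared_samples(mats: dict[str, MethylationMatrix]) -> list[str]:
    its = iter(mats.values())
    samples = list(next(its).samples)
    for mat in its:
        if list(mat.samples) != samples:
            raise ValueError("context matrices must share the sample set and order")
    return samples


def _design(
    mats: dict[str, MethylationMatrix], markers: Sequence[tuple[GenomicInterval, str]]
) -> np.ndarray:
    """Samples x markers design pulled from the per-context matrices."""
    cols = []
    for iv, ctx in markers:
        mat = mats.get(ctx)
        if mat is None:
            raise KeyError(f"no matrix provided for context class {ctx}")
        try:
            j = mat.intervals.index(iv)
        except ValueError:
            raise KeyError(f"interval {iv.id} ({ctx}) missing from matrix") from None
        cols.append(mat.values[:, j])
    return np.column_stack(cols)


@dataclass
class TransferReport:
    n_markers_model: int
    n_markers_used: int
    common_markers: list[str]
    predictions: pd.Series  # per external sample
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_markers_model": self.n_markers_model,
            "n_markers_used": self.n_markers_used,
            "common_markers": self.common_markers,
            "predictions": {k: float(v) for k, v in self.predictions.items()},
            "provenance": self.provenance,
        }


def intersect_markers(
    model: PluripotencyModel, external: MethylationMatrix | ContextMatrices
) -> list[tuple[GenomicInterval, str]]:
    """Model markers covered by the external data, in model order.

    A marker matches only on exact interval identity within its own context
    class.  An empty intersection is an error: the model does not transfer.
    """
    mats = _as_context_map(external)
    common = []
    for iv, ctx in model.markers:
        mat = mats.get(ctx)
        if mat is not None and iv in set(mat.intervals):
            common.append((iv, ctx))
    if not common:
        raise ValueError(
            "no model marker interval is covered by the external data; "
            "check that both datasets use the same window grid"
        )
    return common


def refit_on_common(
    train: MethylationMatrix | ContextMatrices,
    y,
    common: Sequence[tuple[GenomicInterval, str]],
    cfg: ElasticNetConfig = ElasticNetConfig(),
) -> PluripotencyModel:
    """Refit the penalized model on training data restricted to the common
    markers, with the penalty re-selected by seeded CV."""
    if not common:
        raise ValueError("need at least one common marker")
    mats = _as_context_map(train)
    _shared_samples(mats)
    X = _design(mats, common)
    return fit_elastic_net(X, y, cfg, feature_meta=list(common))


def predict_external(
    refit_model: PluripotencyModel,
    external: MethylationMatrix | ContextMatrices,
    n_markers_model: int | None = None,
    provenance: dict | None = None,
) -> TransferReport:
    """Predict external samples' pseudo-times from a common-marker refit."""
    mats = _as_context_map(external)
    samples = _shared_samples(mats)
    X = _design(mats, refit_model.markers)
    yhat = refit_model.intercept + X @ refit_model.coefficients
    preds = pd.Series(yhat, index=samples, name="predicted_pseudo_time")
    return TransferReport(
        n_markers_model=(
            n_markers_model if n_markers_model is not None else len(refit_model.markers)
        ),
        n_markers_used=len(refit_model.markers),
        common_markers=[iv.id for iv, _ in refit_model.markers],
        predictions=preds,
        provenance=provenance or {},
    )


def transfer(
    model: PluripotencyModel,
    train: MethylationMatrix | ContextMatrices,
    y,
    external: MethylationMatrix | ContextMatrices,
    cfg: ElasticNetConfig = ElasticNetConfig(),
    provenance: dict | None = None,
) -> TransferReport:
    """Full transfer path: intersect -> refit on training data -> predict."""
    common = intersect_markers(model, external)
    refit = refit_on_common(train, y, common, cfg)
    prov = dict(provenance or {})
    prov.update({"refit_lambda": refit.lam, "refit_alpha": refit.alpha, "cv_seed": cfg.seed})
    report = predict_external(
        refit, external, n_markers_model=len(model.markers), provenance=prov
    )
    report.n_markers_used = len(common)
    report.common_markers = [iv.id for iv, _ in common]
    return report


# ---------------------------------------------------------------------------
# end-to-end orchestration on synthetic data
# ---------------------------------------------------------------------------

def run_pipeline(
    config,
    window_config=None,
    enet_config: ElasticNetConfig | None = None,
    B: int = 200,
    threshold: int | None = None,
    conversion_cutoff: float = 0.95,
    ftest_cutoff: float = 0.05,
    external_pseudo_times: Mapping[str, Sequence[float]] | None = None,
) -> dict:
    """Simulate -> QC -> quantify -> select -> evaluate -> (optionally) transfer.

    ``config`` is a :class:`~methylotime.synthetic.SyntheticConfig`; the
    window grid defaults to non-overlapping windows equal to the generator's
    marker tiling so planted-marker identity is exact at the feature level.
    Returns a dict with the truth, QC report, matrices, selection reports,
    evaluation metrics and transfer reports keyed by cohort name.
    """
    from .quant import WindowConfig, build_matrix, filter_samples_by_conversion
    from .selection import build_models, marker_matrix
    from .synthetic import external_cohort, simulate_cohort
    from .evaluation import evaluate_model

    if window_config is None:
        window_config = WindowConfig(
            window_size=config.interval_size, step_size=config.interval_size
        )
    if threshold is None:
        threshold = B // 2
    enet_config = enet_config or ElasticNetConfig(seed=config.seed)

    truth, methylomes = simulate_cohort(config)
    retained, qc_report = filter_samples_by_conversion(methylomes, cutoff=conversion_cutoff)
    kept = {sid: methylomes[sid] for sid in retained}
    order = {sid: i for i, sid in enumerate(truth.sample_ids)}
    y = np.array([truth.pseudo_time[order[sid]] for sid in retained])
    groups = [truth.group_label[order[sid]] for sid in retained]

    cpg = build_matrix(kept, config.chrom_sizes, window_config, "CpG")
    noncpg = build_matrix(kept, config.chrom_sizes, window_config, "nonCpG")
    reports = build_models(
        cpg, noncpg, y, enet_config, ftest_cutoff=ftest_cutoff, B=B, threshold=threshold
    )
    out = {
        "truth": truth,
        "qc_report": qc_report,
        "retained_samples": retained,
        "y": y,
        "groups": groups,
        "cpg_matrix": cpg,
        "noncpg_matrix": noncpg,
        "selection": reports,
    }
    combined = reports["combined"].model
    if combined is not None:
        X = marker_matrix(combined, cpg, noncpg)
        out["evaluation"] = evaluate_model(combined, X, y, groups=groups, cfg=enet_config)
        if external_pseudo_times:
            out["transfer"] = {}
            train_mats = {"CpG": cpg, "nonCpG": noncpg}
            for i, (name, times) in enumerate(external_pseudo_times.items()):
                _, ext_meth = external_cohort(
                    config, truth, list(times), prefix=name, seed_offset=1000 + 100 * i
                )
                ext_mats = {
                    "CpG": build_matrix(ext_meth, config.chrom_sizes, window_config, "CpG"),
                    "nonCpG": build_matrix(ext_meth, config.chrom_sizes, window_config, "nonCpG"),
                }
                out["transfer"][name] = transfer(
                    combined, train_mats, y, ext_mats, enet_config, provenance={"cohort": name}
                )
    return out
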