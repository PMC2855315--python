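"""End-to-end convenience: measurements -> QC'd feature matrix -> fitted model."""

from __future__ import annotations

from .data import MeasurementSet
from .features import FeatureConfig, FeatureMatrix, build_feature_matrix, normalize
from .qc import QCResult, apply_mask, cluster_qc


def prepare_features(
    measurements: MeasurementSet,
    config: FeatureConfig | None = None,
    qc_method: str = "centroid",
    run_qc: bool = True,
) -> tuple[FeatureMatrix, QCResult | None]:
    """Extract signatures, run clustering QC, and return the retained raw matrix.

    QC clusters the fully normalized matrix; the returned matrix is the raw
    one with the failing rows dropped, so downstream model fits can freeze
    their own training-set column statistics without leakage.
    """
    raw = build_feature_matrix(measurements, config)
    if not run_qc:
        return raw, None
    normalized = normalize(raw)
    result = cluster_qc(normalized, method=qc_method)
    return apply_mask(raw, result.keep_mask), result
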