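"""Map per-fragment features back to full-length coordinates and flatten them.

Every fragment window contributes its feature vector to the stretch of the
full-length sequence it covers; where windows overlap, the contributions are
flattened with a reducer (arithmetic mean by default, selectable among mean,
median, min and max).  With the orientation feature encoded as parallel = 1
and antiparallel = 0, an integrated value of 0.5 therefore means that half
of the models covering a position were parallel and half antiparallel — a
signature of locally ambiguous topological preference.  The result is a long
table with one row per (position, specification) and one column per feature,
plus a coverage column counting the models that cover each position.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .divide import DivisionManifest
from .errors import IntegrationError
from .features import DEFAULT_KIH_CUTOFF, compute_features
from .model_io import read_model

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("plddt", "pae", "orientation", "kih")

#: reducers usable to flatten overlapping windows; all ignore NaN
REDUCERS: dict[str, Callable[..., np.ndarray]] = {
    "mean": np.nanmean,
    "median": np.nanmedian,
    "min": np.nanmin,
    "max": np.nanmax,
}


def integrate_features(
    manifest: DivisionManifest,
    fragment_features: Mapping[tuple[str, int], Mapping[str, np.ndarray | None]],
    features: Sequence[str] = FEATURE_NAMES,
    reducer: str = "mean",
) -> pd.DataFrame:
    """Flatten per-fragment feature vectors into the per-residue table.

    Parameters
    ----------
    manifest
        The division manifest defining window coordinates.
    fragment_features
        ``(spec_label, fragment_index) -> {feature -> vector or None}``.
        Fragments absent from the mapping (e.g. failed predictions) reduce
        coverage instead of aborting.  A None vector marks a feature missing
        for that fragment; it is excluded from the reduction.
    reducer
        One of ``mean``, ``median``, ``min``, ``max``.

    Returns
    -------
    DataFrame with columns ``position`` (1-based), ``spec_label``, one
    column per feature, and ``coverage``.
    """
    if reducer not in REDUCERS:
        raise ValueError(f"unknown reducer {reducer!r}, expected one of {sorted(REDUCERS)}")
    reduce = REDUCERS[reducer]
    n = manifest.sequence_length
    frames = []
    for spec in manifest.specs:
        windows = manifest.windows[spec.label]
        present = []
        for w in windows:
            key = (spec.label, w.fragment_index)
            if key not in fragment_features:
                logger.warning(
                    "no model features for fragment %s/%d; coverage reduced",
                    spec.label, w.fragment_index,
                )
                continue
            vectors = fragment_features[key]
            for name in features:
                vec = vectors.get(name)
                if vec is not None and len(vec) != w.length:
                    raise IntegrationError(
                        f"fragment {spec.label}/{w.fragment_index}: feature "
                        f"{name!r} has length {len(vec)}, window length is {w.length}"
                    )
            present.append((w, vectors))

        coverage = np.zeros(n, dtype=int)
        for w, _ in present:
            coverage[w.start:w.end] += 1

        data: dict[str, np.ndarray] = {}
        for name in features:
            mat = np.full((max(len(present), 1), n), np.nan)
            for k, (w, vectors) in enumerate(present):
                vec = vectors.get(name)
                if vec is not None:
                    mat[k, w.start:w.end] = vec
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
                data[name] = reduce(mat, axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "position": np.arange(1, n + 1),
                    "spec_label": spec.label,
                    **data,
                    "coverage": coverage,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-residue table as CSV (round-trips values to 1e-6)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.10g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def integrate_run(
    rundir: str | Path,
    models_dir: str | Path,
    features: Sequence[str] = FEATURE_NAMES,
    reducer: str = "mean",
    kih_cutoff: float = DEFAULT_KIH_CUTOFF,
) -> pd.DataFrame:
    """End-to-end integration of a run directory against a models directory.

    Models are located by the query file stem recorded in constructs.csv:
    ``<stem>.pdb`` and, if present, ``<stem>.pae.json`` (or ``<stem>.json``).
    Missing model files are logged and reduce coverage.
    """
    manifest = DivisionManifest.read(rundir)
    models_dir = Path(models_dir)
    flank_length = len(manifest.flank)
    fragment_features: dict[tuple[str, int], dict[str, np.ndarray | None]] = {}
    for spec in manifest.specs:
        for w in manifest.windows[spec.label]:
            stem = manifest.query_file(spec.label, w.fragment_index)[: -len(".fasta")]
            pdb_path = models_dir / f"{stem}.pdb"
            if not pdb_path.exists():
                logger.warning("model file %s missing; skipping fragment", pdb_path)
                continue
            pae_path = None
            for cand in (f"{stem}.pae.json", f"{stem}.json"):
                if (models_dir / cand).exists():
                    pae_path = models_dir / cand
                    break
            model = read_model(
                pdb_path,
                pae_path=pae_path,
                flank_length=flank_length,
                provenance={
                    "query_file": f"{stem}.fasta",
                    "spec_label": spec.label,
                    "fragment_index": w.fragment_index,
                },
            )
            fragment_features[(spec.label, w.fragment_index)] = compute_features(
                model, features=tuple(features), kih_cutoff=kih_cutoff
            )
    return integrate_features(manifest, fragment_features, features=features, reducer=reducer)


def plot_summary(table: pd.DataFrame, path: str | Path) -> Path:
    """Stacked per-feature panels, one trace per specification.

    Purely presentational; panels whose feature column is entirely missing
    are omitted with a logged notice.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if table.empty:
        raise ValueError("cannot plot an empty feature table")
    feature_cols = [
        c for c in table.columns
        if c not in ("position", "spec_label", "coverage")
    ]
    keep = []
    for c in feature_cols:
        if table[c].notna().any():
            keep.append(c)
        else:
            logger.info("feature %r has no values; panel omitted", c)
    fig, axes = plt.subplots(
        len(keep), 1, sharex=True, figsize=(10, 2.2 * max(len(keep), 1)), squeeze=False
    )
    for ax, name in zip(axes[:, 0], keep):
        for label, sub in table.groupby("spec_label"):
            ax.plot(sub["position"], sub[name], label=str(label), lw=1)
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("residue position")
    axes[0, 0].legend(fontsize="small", ncol=4)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
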