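"""Model/Results interface to the hashtag classifier.

`CellHashingModel` holds the data and tuning parameters; `fit()` runs the
full pipeline (CLR → k-medoids → NB backgrounds → thresholds → calls) and
returns a `CellHashingResults` carrying the per-barcode classification, the
fitted background model, diagnostics and a text `summary()`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import TagCountMatrix
from . import demux as _demux
from .demux import BackgroundModel

__all__ = ["CellHashingModel", "CellHashingResults"]


class CellHashingModel:
    """Hashtag demultiplexing model for a barcode × tag UMI count matrix.

    Parameters
    ----------
    counts : TagCountMatrix or DataFrame
        Raw HTO UMI counts, barcodes × tags.
    rna_umi : Series, optional
        Per-barcode transcriptome UMI totals. When given, barcodes below
        ``min_rna_umi`` are held out of fitting and classification and can
        be rescued from the fitted results.
    k : int, optional
        Number of k-medoids clusters; defaults to n_tags + 1 (one cluster
        per hashtag plus a background cluster).
    q : float
        Background quantile defining positivity (default 0.99).
    outlier_fraction : float
        Fraction of highest background counts dropped before the NB fit
        (default 0.005).
    min_rna_umi : int
        Inclusion cutoff on RNA UMIs (default 200).
    pseudocount : int
        Added inside the CLR transform (default 1).
    """

    def __init__(
        self,
        counts,
        rna_umi=None,
        k=None,
        q=0.99,
        outlier_fraction=0.005,
        min_rna_umi=200,
        pseudocount=1,
    ):
        if isinstance(counts, TagCountMatrix):
            self.counts = counts
        else:
            self.counts = TagCountMatrix.from_dataframe(pd.DataFrame(counts))
        self.rna_umi = None if rna_umi is None else pd.Series(rna_umi)
        self.k = k
        self.q = q
        self.outlier_fraction = outlier_fraction
        self.min_rna_umi = min_rna_umi
        self.pseudocount = pseudocount

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rna_umi=None, **kwargs):
        """Build from a dense DataFrame (index barcodes, columns tags)."""
        return cls(TagCountMatrix.from_dataframe(df), rna_umi=rna_umi, **kwargs)

    @classmethod
    def from_mtx(cls, path, rna_umi=None, **kwargs):
        """Build from an MTX directory (matrix.mtx + barcodes/features.tsv)."""
        from .io import read_count_matrix

        return cls(read_count_matrix(path), rna_umi=rna_umi, **kwargs)

    def fit(self, seed: int = 0, kmedoids_subsample: int = 2000) -> "CellHashingResults":
        """Run the demultiplexing pipeline; returns fitted results."""
        classification, background, diagnostics = _demux.demultiplex(
            self.counts,
            rna_umi=self.rna_umi,
            k=self.k,
            q=self.q,
            outlier_fraction=self.outlier_fraction,
            min_rna_umi=self.min_rna_umi,
            pseudocount=self.pseudocount,
            seed=seed,
            kmedoids_subsample=kmedoids_subsample,
        )
        return CellHashingResults(self, classification, background, diagnostics, seed)


class CellHashingResults:
    """Fitted hashtag classification.

    Attributes
    ----------
    classification : DataFrame
        Indexed by barcode; ``global_class`` (singlet/multiplet/negative),
        ``hash_id`` and ``n_positive_tags``.
    background : BackgroundModel
        Per-tag NB parameters, thresholds and the frozen CLR transform.
    diagnostics : dict
        Class counts, thresholds, cluster sizes and parameters used.
    """

    def __init__(self, model, classification, background, diagnostics, seed):
        self.model = model
        self.classification = classification
        self.background = background
        self.diagnostics = diagnostics
        self.seed = seed

    @property
    def thresholds(self) -> pd.Series:
        return pd.Series(
            self.background.thresholds, index=self.background.tags, name="threshold"
        )

    @property
    def counts_by_class(self) -> dict:
        return dict(self.diagnostics["counts_by_class"])

    def rescue(self, low: int = 50, high: int = 200) -> pd.DataFrame:
        """Rescue low-RNA barcodes (UMIs in [low, high)) with frozen thresholds."""
        if self.model.rna_umi is None:
            raise ValueError(
                "rescue requires rna_umi totals on the model; none were given"
            )
        return _demux.rescue_low_umi(
            self.model.counts, self.background, self.model.rna_umi, low, high
        )

    def normalized(self) -> pd.DataFrame:
        """CLR values of the classified barcodes under the frozen transform."""
        sub = self.model.counts.to_dataframe().loc[self.classification.index]
        return self.background.normalize(sub)

    def summary(self) -> str:
        d = self.diagnostics
        cls = d["counts_by_class"]
        n = d["n_barcodes_classified"]
        lines = [
            "          Cell Hashing classification summary",
            "=" * 56,
            f"Barcodes classified: {n:>10d}    k-medoids k: {d['params']['k']}",
            f"Quantile q:          {d['params']['q']:>10.3f}    seed: {self.seed}",
            "-" * 56,
            f"{'class':<12}{'count':>10}{'fraction':>12}",
        ]
        for c in ("singlet", "multiplet", "negative"):
            frac = cls.get(c, 0) / n if n else 0.0
            lines.append(f"{c:<12}{cls.get(c, 0):>10d}{frac:>12.4f}")
        lines.append("-" * 56)
        lines.append(f"{'tag':<12}{'NB mean':>10}{'NB size':>10}{'threshold':>11}")
        for e in self.background.entries:
            size = "inf" if np.isinf(e.nb_size) else f"{e.nb_size:.3f}"
            lines.append(
                f"{e.tag:<12}{e.nb_mean:>10.3f}{size:>10}{e.threshold:>11d}"
            )
        lines.append("=" * 56)
        return "\n".join(lines)

    def to_files(self, outdir) -> None:
        """Write classification TSV + thresholds JSON (see hashdemux.io)."""
        from .io import write_classification

        write_classification(
            self.classification, self.background, outdir,
            counts=self.model.counts,
        )

    def __repr__(self):
        cls = self.diagnostics["counts_by_class"]
        return (
            f"<CellHashingResults: {cls.get('singlet', 0)} singlets, "
            f"{cls.get('multiplet', 0)} multiplets, "
            f"{cls.get('negative', 0)} negatives>"
        )
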