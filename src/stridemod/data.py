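"""Shared in-memory containers and text-format readers/writers.

The central object is :class:`ExpressionData`: a probes x samples matrix
(pandas DataFrame) paired with a sample sheet describing each array
(drug, time point, hybridization batch, treatment arm, replicate).
All disk formats are plain text: TSV for matrices, CSV for sample
sheets and phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Sample-sheet columns, in canonical order.
SAMPLE_COLUMNS = ["sample_id", "drug", "time_h", "batch", "arm", "replicate"]

#: Reserved control labels used throughout the pipeline.
SALINE = "saline"
NAIVE = "naive"


@dataclass
class ExpressionData:
    """Expression matrix plus per-sample annotations.

    Parameters
    ----------
    values
        probes x samples matrix. Index = probe IDs, columns = sample IDs.
    samples
        Sample sheet with one row per array; must contain
        :data:`SAMPLE_COLUMNS` and cover exactly the matrix columns.
    log2
        Whether ``values`` is on the log2 scale (True) or raw
        intensity scale (False).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log2: bool = True
    #: residual degrees of freedom per probe consumed by upstream
    #: transforms (e.g. within-batch centering); honored by the ANOVA.
    df_adjustment: int = 0

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        mat_cols = list(self.values.columns)
        sheet_ids = list(self.samples["sample_id"])
        if set(mat_cols) != set(sheet_ids):
            raise ValueError("sample sheet does not match matrix columns")
        if len(set(sheet_ids)) != len(sheet_ids):
            raise ValueError("duplicate sample IDs")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe IDs")
        # keep sheet ordered like the matrix
        order = {s: i for i, s in enumerate(mat_cols)}
        self.samples = (
            self.samples.sort_values("sample_id", key=lambda s: s.map(order))
            .reset_index(drop=True)
        )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, mask: pd.Series) -> "ExpressionData":
        """Restrict to samples where ``mask`` (indexed like the sheet) holds."""
        keep = self.samples.loc[mask.values, "sample_id"].tolist()
        return ExpressionData(
            self.values[keep], self.samples[self.samples.sample_id.isin(keep)],
            log2=self.log2, df_adjustment=self.df_adjustment,
        )

    def copy(self) -> "ExpressionData":
        return ExpressionData(self.values.copy(), self.samples.copy(),
                              self.log2, self.df_adjustment)


@dataclass
class PhenotypeTable:
    """Behavioral readouts keyed by drug.

    ``cpp`` holds one conditioned-place-preference score per drug;
    ``locomotion`` holds activity counts per drug x time bin (hours).
    """

    cpp: pd.Series
    locomotion: pd.DataFrame  # index = drug, columns = time_h

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        long = self.locomotion.stack().rename("locomotion").reset_index()
        long.columns = ["drug", "time_h", "locomotion"]
        cpp = self.cpp.rename("cpp").reset_index()
        cpp.columns = ["drug", "cpp"]
        merged = long.merge(cpp, on="drug", how="left")
        merged.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhenotypeTable":
        df = pd.read_csv(path)
        cpp = df.drop_duplicates("drug").set_index("drug")["cpp"]
        loco = df.pivot(index="drug", columns="time_h", values="locomotion")
        return cls(cpp=cpp, locomotion=loco)


def write_expression_tsv(data: ExpressionData, matrix_path: str | Path,
                         samples_path: str | Path) -> None:
    """Write the matrix as TSV (probes in rows) and the sheet as CSV."""
    data.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
    data.samples[SAMPLE_COLUMNS].to_csv(samples_path, index=False)


def read_expression_tsv(matrix_path: str | Path, samples_path: str | Path,
                        log2: bool = True) -> ExpressionData:
    values = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
    samples = pd.read_csv(samples_path)
    return ExpressionData(values=values, samples=samples, log2=log2)
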