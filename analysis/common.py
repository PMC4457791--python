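"""Shared configuration for the numbered analysis drivers.

One study seed governs every stage; each driver regenerates what it needs
deterministically from that seed and reads/writes small tables under
``results/``. Spectra themselves are not persisted (they are large and
exactly reproducible from the seed).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from serumpep.pipeline import StudyConfig
from serumpep.preprocess import FeatureMatrix, PeakDefinition

STUDY = StudyConfig(seed=1)
RESULTS = Path(__file__).resolve().parent.parent / "results"


def save_feature_matrix(fm: FeatureMatrix, stem: str) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    fm.to_dataframe().to_csv(RESULTS / f"{stem}_features.csv", index=False)
    pd.DataFrame([vars(p) for p in fm.peak_definitions]).to_csv(
        RESULTS / f"{stem}_peaks.csv", index=False)


def load_feature_matrix(stem: str) -> FeatureMatrix:
    df = pd.read_csv(RESULTS / f"{stem}_features.csv")
    pk = pd.read_csv(RESULTS / f"{stem}_peaks.csv")
    defs = [PeakDefinition(r.centroid, r.left_bound, r.right_bound, int(r.index))
            for r in pk.itertuples(index=False)]
    meta = ["sample_id", "qc_flag"]
    areas = df[[c for c in df.columns if c not in meta]].to_numpy(float)
    return FeatureMatrix(df["sample_id"].tolist(), defs, areas,
                         df["qc_flag"].tolist())


def load_labels(stem: str, sample_ids) -> np.ndarray:
    cohort = pd.read_csv(RESULTS / f"{stem}_cohort.csv").set_index("sample_id")
    return cohort.loc[list(sample_ids), "true_class"].to_numpy()
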