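"""Stage 3: differential peak statistics on the training cohort."""

from serumpep.stats import differential_peaks

from common import RESULTS, load_feature_matrix, load_labels

if __name__ == "__main__":
    fm = load_feature_matrix("training")
    labels = load_labels("training", fm.sample_ids)
    table = differential_peaks(fm, labels)
    table.to_csv(RESULTS / "differential_peaks.csv", index=False)
    sig = table[table["significant"]]
    print(f"{len(sig)} of {len(table)} peaks significant after "
          f"Benjamini-Hochberg control")
    cols = ["centroid", "mean_mutant", "mean_wild", "p_welch", "p_welch_bh",
            "direction"]
    print(sig.sort_values("p_welch")[cols].head(10).to_string(index=False))
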