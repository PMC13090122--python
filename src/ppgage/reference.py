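"""Published UK Biobank reference results for single-pulse PPG age prediction.

These numbers come from the gated UK Biobank accession (~170k finger PPG
pulses, ages 40-70) and are carried here as *reference annotations only*:
they are not reproducible from synthetic data and nothing in this package
computes them.  They anchor the qualitative pattern the synthetic analyses
reproduce — every predictor, deep or ASI-based, lands only slightly better
than predicting the mean age.

Each entry is (mean, sd) over fivefold cross-validation; a Spearman rho of
None marks the constant mean-baseline predictor, for which rank correlation
is undefined (reported as "N/A").
"""

UK_BIOBANK_TABLE1 = {
    "smolk": {"mse": (51.77, 0.32), "mae": (5.97, 0.02), "spearman_rho": (0.44, 0.00)},
    "resnet": {"mse": (42.47, 0.60), "mae": (5.24, 0.05), "spearman_rho": (0.57, 0.00)},
    "asi_linear": {"mse": (64.88, 0.46), "mae": (6.85, 0.01), "spearman_rho": (0.20, 0.00)},
    "asi_gam": {"mse": (63.58, 0.12), "mae": (6.78, 0.01), "spearman_rho": (0.20, 0.00)},
    "mean_baseline": {"mse": (66.52, 0.35), "mae": (6.98, 0.02), "spearman_rho": None},
}

#: Printed UK Biobank ASI summary statistics (m/s) used to calibrate the
#: synthetic generator.
UK_BIOBANK_ASI_SUMMARY = {
    "median_age_40": 7.3,
    "median_age_50": 8.4,
    "median_age_70": 9.9,
    "q3_age_40": 8.8,
}
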