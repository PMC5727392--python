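"""Feature comparisons between drug-retained and non-regulated introns.

Simulates a retained-intron cohort at the default study conditions,
quantifies the drug response, and contrasts 3'ss sequence features
between regulated and non-regulated events with Mann-Whitney tests —
the transcriptome-wide analysis the package exists for.
"""

from branchsense import compare_features, mann_whitney_u, quantify
from branchsense.pipeline import compute_features
from branchsense.synthetic_data import SimParams, generate_event_set

sim = generate_event_set(SimParams(seed=1, n_events=1000, ir_fraction=1.0))
features = compute_features(sim.introns)
q = quantify(sim.table, ["CTRL_1", "CTRL_2"], ["TRT_1", "TRT_2"])
merged = features.merge(q, on="EVENT_ID")

cmp = compare_features(
    merged.set_index("EVENT_ID")[
        ["bp_best_pairing", "ppt_score", "gc_intron", "len_intron", "bp_distance"]],
    merged["event_class"].values, "regulated_up", "nondiff")
print(cmp[["feature", "n1", "n2", "median1", "median2", "p_value", "stars"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))

covered = merged.dropna(subset=["delta"])
single = covered.loc[covered["n_bp_matches_100"] == 1, "delta"]
multi = covered.loc[covered["n_bp_matches_100"] >= 2, "delta"]
mb = mann_whitney_u(multi, single)
print()
print(f"multi-BP events: median dPIR {mb.median1:.1f} (n={mb.n1}) vs "
      f"single-BP {mb.median2:.1f} (n={mb.n2}), p={mb.p_value:.2g}")
print()
print("Retained introns are shorter, more GC-rich and carry weaker BPs and")
print("Py-tracts than unaffected ones (median1 vs median2); extra BP")
print("consensus matches 5' of the branch point protect against retention.")
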