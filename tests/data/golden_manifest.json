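{
  "config": {
    "adj_p_max": 0.05,
    "already_normalized": true,
    "decoy_fraction": 0.3,
    "min_delta_beta": 0.2,
    "min_detection": 0.6,
    "min_fold_change": 2.0,
    "moderated": false,
    "n_perm": 1000,
    "outdir": "scratch/golden",
    "pair_alpha": 0.05,
    "pair_alpha_on": "p",
    "pair_r_cut": 0.5,
    "require_lncrna_mrna_edge": false,
    "run_enrichment": true,
    "seed": 7,
    "simulation": {
      "activity_sd": 0.75,
      "activity_shift": 2.5,
      "beta_noise_sd": 0.05,
      "beta_shift": -0.25,
      "de_log2fc": 1.5,
      "n_case": 20,
      "n_confounded": 18,
      "n_control": 20,
      "n_cpg_genes": 200,
      "n_lncrna": 200,
      "n_mirna": 200,
      "n_mrna": 200,
      "n_planted_de": 20,
      "n_planted_hypo_up": 2,
      "n_planted_triads": 5,
      "n_reference_pairs": 10,
      "noise_sd": 0.5,
      "seed": 7,
      "tissue_offset": 2.0,
      "triad_coupling": 0.8
    },
    "weight_p": 1.0
  },
  "counts": {
    "differential": {
      "lncRNA": {
        "significant": 31,
        "tested": 200
      },
      "mRNA": {
        "significant": 33,
        "tested": 200
      },
      "methylation": {
        "significant": 2,
        "tested": 200
      },
      "miRNA": {
        "significant": 31,
        "tested": 200
      }
    },
    "enrichment": {
      "gba_hub": "miR-0179",
      "gba_sets": 11,
      "ora_sets": 11,
      "ora_significant": 3
    },
    "network": {
      "pairs_predicted": {
        "mirna_lncrna": 168,
        "mirna_mrna": 83
      },
      "pairs_thresholded": {
        "lncrna_mrna": 311,
        "mirna_lncrna": 550,
        "mirna_mrna": 278
      },
      "triads": 321
    },
    "preprocess": {
      "lncRNA": 200,
      "mRNA": 200,
      "miRNA": 200
    },
    "quadrant": {
      "counts": {
        "1": 0,
        "2": 0,
        "3": 2,
        "4": 9,
        "5": 167,
        "6": 22,
        "7": 0,
        "8": 0,
        "9": 0
      },
      "hypo_up": [
        "G0050",
        "G0164"
      ],
      "matched_genes": 200
    },
    "reference_filter": {
      "lncRNA": {
        "after": 24,
        "before": 31
      },
      "mRNA": {
        "after": 24,
        "before": 33
      },
      "miRNA": {
        "after": 23,
        "before": 31
      }
    },
    "simulate": {
      "features": {
        "lncRNA": 200,
        "mRNA": 200,
        "methylation": 200,
        "miRNA": 200
      },
      "gene_sets": 11,
      "n_samples": 40,
      "predictions": 24007
    }
  },
  "seed": 7,
  "version": "0.1.0"
}
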