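# Independent oracle used to freeze the expected values in
# tests/test_mlmeta.py::test_matches_metafor_on_frozen_fixture and
# tests/test_bias.py::test_matches_metafor_on_frozen_fixture.
#
# Regenerate the inputs with:
#   python - <<'PY'
#   from phylometa import synthetic_data, phylo, effects_io
#   for seed, n_sp, n_st, n_est, stem in [(11, 5, 8, 20, "oracle"),
#                                          (21, 18, 43, 104, "oracle2")]:
#       cfg = synthetic_data.SimulationConfig(
#           n_species=n_sp, n_studies=n_st, n_estimates=n_est, seed=seed)
#       tree = synthetic_data.simulate_tree(n_sp, seed)
#       recs, _ = synthetic_data.simulate_dataset(cfg, tree=tree)
#       effects_io.write_records(recs, f"{stem}.csv")
#       phylo.phylo_correlation(tree).write_tsv(f"{stem}_A.tsv")
#   PY
# then run this script from the directory holding the CSV/TSV files.

suppressMessages(library(metafor))

run <- function(stem) {
  d <- read.csv(paste0(stem, ".csv"))
  A <- as.matrix(read.delim(paste0(stem, "_A.tsv"), row.names = 1,
                            check.names = FALSE))
  d$phylo <- d$species
  d$sp <- d$species
  fit <- rma.mv(h2, sampling_variance,
                random = list(~1 | study_id, ~1 | phylo, ~1 | sp,
                              ~1 | estimate_id),
                R = list(phylo = A), data = d, method = "REML")
  cat(stem, "intercept-only sigma2:", fit$sigma2, "\n")
  cat(stem, "beta:", fit$beta, "se:", fit$se, "ll:", logLik(fit), "\n")
  d
}

run("oracle")
d <- run("oracle2")

eg <- rma.mv(h2, sampling_variance, mods = ~sampling_variance,
             random = list(~1 | study_id, ~1 | sp, ~1 | estimate_id),
             data = d, method = "REML")
cat("oracle2 egger slope:", eg$beta[2], "se:", eg$se[2], "p:", eg$pval[2], "\n")
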