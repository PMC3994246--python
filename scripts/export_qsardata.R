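#!/usr/bin/env Rscript
# Export the QSARdata package's benchmark tables to the CSV layout this
# package reads (one output column named "y", remaining columns numeric
# descriptors).  Requires install.packages("QSARdata").  Optional helper:
# the library itself never reads R serialisation formats.
#
# Usage: Rscript scripts/export_qsardata.R <output-directory>

suppressMessages(library(QSARdata))

args <- commandArgs(trailingOnly = TRUE)
outdir <- if (length(args) >= 1) args[1] else "qsardata_csv"
dir.create(outdir, showWarnings = FALSE, recursive = TRUE)

export <- function(desc, outcome, name) {
  stopifnot(nrow(desc) == length(outcome))
  num <- desc[, sapply(desc, is.numeric), drop = FALSE]
  df <- cbind(y = outcome, num)
  path <- file.path(outdir, paste0(name, ".csv"))
  write.csv(df, path, row.names = FALSE)
  cat(sprintf("%s: %d rows, %d descriptors\n", path, nrow(df), ncol(num)))
}

data(AquaticTox)
export(AquaticTox_moe2D[, -1], AquaticTox_Outcome$Activity, "AquaticTox_moe2D")

data(bbb2)
keep <- complete.cases(bbb2_Lcalc)
export(bbb2_Lcalc[keep, -1], bbb2_Outcome$Class[keep], "bbb2_Lcalc")

data(caco)
export(caco_PipelinePilotFP[, -1], caco_Outcome$Class, "caco_PipelinePilotFP")
export(caco_QuickProp[, -1], caco_Outcome$Class, "caco_QuickProp")

data(MeltingPoint)
export(MP_Descriptors, MP_Outcome, "MeltingPoint")

data(Mutagen)
export(Mutagen_Dragon, Mutagen_Outcome, "Mutagen_Dragon")

data(PLD)
export(PLD_PipelinePilotFP[, -1], PLD_Outcome$Class, "PLD_PipelinePilotFP")
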