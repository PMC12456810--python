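# Gamma log-link mixed model for the within/between entropy-symptom
# association: SC regressed on person-mean H and mean-centered H with a
# participant random intercept (maximum likelihood, Laplace approximation).
# A random slope of centered H is retained when the likelihood-ratio test
# favors it at p < .05.  Called with: Rscript wb_glmm.R <in.csv> <out.json>

args <- commandArgs(trailingOnly = TRUE)
infile <- args[1]
outfile <- args[2]

dat <- read.csv(infile)
dat$participant_id <- factor(dat$participant_id)

f0 <- SC ~ person_mean_H + centered_H + (1 | participant_id)
f1 <- SC ~ person_mean_H + centered_H + (1 + centered_H | participant_id)

backend <- "lme4"
fit_one <- function(formula) {
  suppressWarnings(suppressMessages(
    lme4::glmer(formula, data = dat, family = Gamma(link = "log"))
  ))
}
m0 <- try(fit_one(f0), silent = TRUE)
if (inherits(m0, "try-error")) {
  backend <- "glmmTMB"
  fit_one <- function(formula) {
    suppressWarnings(suppressMessages(
      glmmTMB::glmmTMB(formula, data = dat, family = Gamma(link = "log"))
    ))
  }
  m0 <- fit_one(f0)
}

use_slope <- FALSE
lrt_p <- NA
m <- m0
m1 <- try(fit_one(f1), silent = TRUE)
if (!inherits(m1, "try-error")) {
  a <- try(suppressMessages(anova(m0, m1)), silent = TRUE)
  if (!inherits(a, "try-error")) {
    pcol <- grep("Pr", names(a), value = TRUE)[1]
    lrt_p <- a[[pcol]][nrow(a)]
    if (!is.na(lrt_p) && lrt_p < 0.05) {
      m <- m1
      use_slope <- TRUE
    }
  }
}

if (backend == "lme4") {
  co <- summary(m)$coefficients
} else {
  co <- summary(m)$coefficients$cond
}
terms <- c("person_mean_H", "centered_H")
res <- list()
for (term in terms) {
  est <- co[term, "Estimate"]
  se <- co[term, "Std. Error"]
  p <- co[term, ncol(co)]
  res[[term]] <- list(
    estimate = est,
    se = se,
    conf_low = est - 1.959963984540054 * se,
    conf_high = est + 1.959963984540054 * se,
    p_value = p
  )
}
out <- list(
  terms = res,
  n_obs = nrow(dat),
  n_participants = length(unique(dat$participant_id)),
  random_slope = use_slope,
  lrt_p = lrt_p,
  backend = backend
)
writeLines(jsonlite::toJSON(out, auto_unbox = TRUE, digits = 12, na = "null"),
           outfile)
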