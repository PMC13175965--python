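# faersig

Disproportionality signal mining for spontaneous adverse-event report
databases in the FAERS quarterly-extract format.

## The problem

Spontaneous reporting systems such as the FDA Adverse Event Reporting System
(FAERS) collect millions of post-marketing safety reports. Screening them
for drug–event associations — for example, the immune-related adverse
events (irAEs) of immune checkpoint inhibitors (ICIs), which can strike any
organ system — requires a reproducible pipeline: collapse versioned case
reports to one record per case, drop reports from non-health-professionals,
restrict to reports naming the drug of interest as the primary suspect,
roll MedDRA Preferred Terms (PT) up to Standardised MedDRA Queries (SMQ)
and System Organ Classes (SOC), and compare each (drug, term) pair's
observed reporting frequency with its expectation under independence.

`faersig` implements that pipeline end to end, plus a synthetic report
generator with planted signals so every stage is testable without the
multi-gigabyte (and licensed-vocabulary-dependent) real data.

## The statistics

For each (drug, term) pair, with `a/b/c/d` the report counts of the 2×2
table against the cleaned background database, `N = a+b+c+d` and
`E = (a+b)(a+c)/N`:

- **ROR** — reporting odds ratio `ad/bc` with Wald 95% CI on the log scale
  (Haldane–Anscombe +0.5 on zero cells); positive when ROR025 > 1.
- **PRR / MHRA** — proportional reporting ratio `(a/(a+b))/(c/(c+d))` with
  the Yates-corrected χ²; positive when PRR ≥ 2, χ² ≥ 4 and a ≥ 3.
- **BCPNN IC** — information component `log2((a+0.5)/(E+0.5))` with its
  2.5% credible bound IC025 from the Gamma(a+0.5, rate 1) posterior of the
  shrunk count; positive when IC025 > 0, with intensity bands
  weak (0 < IC025 ≤ 1.5), moderate (1.5 < IC025 ≤ 3.0), strong (IC025 > 3.0).
- **MGPS / EBGM** — a two-component gamma mixture prior on the relative
  reporting rate λ (a ~ Poisson(λE)), fitted by maximising the
  negative-binomial-mixture marginal likelihood; EBGM is the posterior
  geometric mean and EBGM05 its 5th percentile; positive when EBGM05 > 2.

Every method additionally requires at least three target reports.
Cumulative metrics (C-ROR025, C-IC025, C-EBGM05) sum a term's lower-bound
statistic over the drugs flagged positive, ranking terms by class-wide
signal intensity.

## Worked example

```python
from faersig import (SyntheticConfig, generate, deduplicate, filter_reporters,
                     select_primary_suspect, build_tables, score_tables,
                     screen_signals)
from faersig.cleaning import default_ici_synonyms
from faersig.meddra import load_hierarchy, fixture_hierarchy_paths

cfg = SyntheticConfig(n_cases=20_000, seed=7,
                      rr={("nivolumab", "Hypophysitis"): 10.0})
records, truth = generate(cfg)                    # FAERS-format tables
background = filter_reporters(deduplicate(records))
annotated = select_primary_suspect(background, default_ici_synonyms())
hier = load_hierarchy(*fixture_hierarchy_paths())
tables = build_tables(background, annotated.annotations, hier, level="PT")
res = screen_signals(score_tables(tables, fit_prior=True))
row = res.set_index(["drug", "term"]).loc[("nivolumab", "Hypophysitis")]
print(f"a={row.a:.0f} ROR025={row.ror_lo:.2f} IC025={row.ic_lo:.2f} "
      f"EBGM05={row.ebgm_lo:.2f} band={row.band}")
```

prints

```
a=463 ROR025=8.05 IC025=1.13 EBGM05=2.39 band=weak
```

— the planted pair (relative reporting rate 10) is seen on 463 deduplicated
professional reports and is flagged positive by every method: the lower 95%
bound of its reporting odds ratio is 8.05 (well above 1), the information
component's credible bound is positive at 1.13 (a weak-band intensity,
because this fixture PT is common enough that its expected count is already
large), and the shrunken empirical-Bayes EBGM05 of 2.39 clears the >2 rule.

The same workflow is scriptable from the shell:

```
faersig simulate --n-cases 20000 --seed 7 --out-dir data/
faersig signal data/DEMO.txt data/DRUG.txt data/REAC.txt data/OUTC.txt \
        data/THER.txt --level PT --out signals.csv
faersig run-all --config run.json
```

## Layout

| module | contents |
|---|---|
| `faersig.io` | FAERS "$"-dialect readers/writers, date precision, age units |
| `faersig.cleaning` | deduplication, reporter filter, primary-suspect selection |
| `faersig.meddra` | hierarchy loading, PT→SMQ/SOC roll-up |
| `faersig.contingency` | 2×2 table construction against the background |
| `faersig.dispro` | ROR, PRR/MHRA, BCPNN, MGPS engines + screening |
| `faersig.aggregate` | cumulative metrics, death proportions, overlap |
| `faersig.characteristics` | demographics, time to onset |
| `faersig.synthetic` | report generator with planted ground truth |
| `faersig.pipeline` / `faersig.cli` | staged orchestration and CLI |

See `docs/methods.md` for the modelling assumptions and design choices.
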