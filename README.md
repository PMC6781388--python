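# rorscreen

Reporting-odds-ratio (ROR) signal screening for spontaneous
adverse-event reporting databases in the JADER three-table layout.

Spontaneous reporting systems (JADER in Japan, FAERS in the US) collect
voluntarily submitted case reports of suspected adverse drug reactions as
linked tables: DEMO (one row per submitted case), DRUG (medications per
case, classified as suspected / concomitant / interaction), and REAC
(adverse events per case, coded as MedDRA Preferred Terms). Pharmacists
and pharmacoepidemiologists screen such databases for *signals* —
drug–event pairs reported disproportionately often. `rorscreen` provides
that screen end to end: ingestion and validation of the three tables,
removal of duplicate case submissions, case linkage, analysis-window
filtering, grouping of Preferred Terms into named event classes, and ROR
estimation with Wald confidence intervals — plus a seeded synthetic
database generator with known ground-truth association strengths, so the
whole pipeline is testable without access to a real release.

## The statistic

For target drug *g* and event class *E*, counting distinct
(case, suspected drug, Preferred Term) co-occurrences:

|             | event in E | other events |
|-------------|-----------:|-------------:|
| drug *g*    | a          | b            |
| other drugs | c          | d            |

ROR = ad / bc,  95% CI = exp( ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) )

A pair is a **signal** when the lower CI bound exceeds 1. Zero cells are
handled with the Haldane–Anscombe correction (0.5 added to every cell,
flagged in the output). The ROR measures disproportionate *reporting*,
not clinical risk; see `docs/methods.md` for assumptions, counting-unit
choices, and limitations.

## Worked example

Generate a synthetic database with a planted association structure
(an originator biologic and its biosimilar among background
immunosuppressants, with the originator's strongest planted association
on tuberculosis), then screen it:

```python
import rorscreen as rs

fx = rs.make_paper_like_fixture()          # 2,000 cases, fixed seed
db = rs.link_tables(rs.deduplicate(fx.demo), fx.drug, fx.reac)
events = rs.load_default_dictionary()      # 5 infection event classes
results = rs.screen(db, events, list(fx.target_drugs))
print(rs.signals_frame(results)[["drug", "event_class", "n", "ror",
                                 "ci_low", "ci_high", "signal"]])
```

```
               drug                event_class   n       ror    ci_low   ci_high  signal
0    IFX originator               Tuberculosis  82  3.101350  2.219957  4.332684    True
1    IFX originator                  Pneumonia  39  1.843743  1.206702  2.817090    True
2    IFX originator                  Infection  23  2.422099  1.367700  4.289363    True
3    IFX originator  Interstitial lung disease   9  1.232484  0.555309  2.735442   False
4    IFX originator                     Sepsis   9  1.911563  0.809175  4.515800   False
5  IFX biosimilar 1               Tuberculosis  39  2.161905  1.444175  3.236334    True
6  IFX biosimilar 1                  Pneumonia  23  2.021493  1.228596  3.326099    True
7  IFX biosimilar 1                  Infection   7  1.025169  0.453199  2.319006   False
8  IFX biosimilar 1  Interstitial lung disease   5  1.320312  0.496596  3.510350   False
9  IFX biosimilar 1                     Sepsis   5  1.876838  0.682914  5.158072   False
```

`n` is the co-occurrence count in cell *a*; tuberculosis tops the
originator's ranking because it carries the largest planted odds
multiplier (the tiny five-drug catalog compresses the magnitudes — see
the methods note). Event-class shares of a drug's total co-occurrences
are computed with `rs.event_class_share(n_class, n_total)`, e.g.
`event_class_share(657, 2771)` → `23.7` (percent, one decimal).

The same run is available from the shell:

```sh
rorscreen screen --demo demo.csv --drug drug.csv --reac reac.csv \
    --target "IFX originator" --target "IFX biosimilar 1" \
    --window-start 2014Q3 --window-end 2018Q4 --out signals.csv
rorscreen report --signals signals.csv
```

and `rorscreen simulate --config sim.yaml --out-dir db/` writes a
synthetic three-table database with a `ground_truth.json` sidecar.

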