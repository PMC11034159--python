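# rootcea

Cost-effectiveness analysis of regular 5% sodium-fluoride varnish
application for preventing **root caries in elderly people**, built as a
reusable, tested Python package. Root caries — decay on exposed root
surfaces — is highly prevalent in elders with gingival recession;
fluoride varnish lowers the onset risk but must be applied repeatedly,
so whether prevention pays off is a genuine health-economic question.

The package is aimed at health-economics and dental-public-health
researchers who want a transparent, scriptable alternative to
spreadsheet or GUI decision-tree tools: every model quantity is
reproducible from code, and every modelling convention is explicit and
testable.

## The model

A tooth-level Markov cohort model: a 60-year-old subject with 23
independent teeth is followed over 20 annual cycles through the states

`INTACT → UNTREATED_CARIES → {FILLED, CROWNED, EXTRACTED}`

with annual onset probability `p_car = 0.007` (multiplied by a risk
ratio `rr = 0.396` under quarterly varnish), restoration/extraction
probabilities for active caries, an endodontic + crown sub-tree within
restorations, and an annual refill risk for fillings. Costs are 2023
Chinese public-healthcare fees (CNY); the effect is the discounted
**root-caries-free tooth year**, with closed form
`E = N·Σ_t ((1−p)/(1+r))^t`. Strategies are compared by the incremental
cost-effectiveness ratio

`ICER = ΔC / ΔE`,

judged against a willingness-to-pay of ¥214 per tooth year (the price
of one filling). One-way sensitivity analysis, threshold (bisection)
analysis, and a 1000-iteration probabilistic sensitivity analysis
(beta-distributed probabilities, gamma-distributed costs with SD =
mean) complete the picture. A microsimulation twin of the cohort engine
doubles as a stochastic oracle and as a generator of synthetic
longitudinal exam panels from which transition probabilities can be
re-estimated (parameter recovery, including multi-year exam intervals).
See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```bash
$ rootcea base-case --out-dir out
ICER: 161.16 CNY per root-caries-free tooth year
```

The report `out/base_case.json` shows both arms: the control accrues
269.46 discounted root-caries-free tooth years at ¥1068.97, the
fluoride programme 279.67 tooth years at ¥2713.52 — 10.20 tooth years
gained for an extra ¥1644.54, i.e. ¥161.16 per tooth year, below the
¥214 threshold, so the programme is cost-effective in the base case
(but not dominant: it buys health, it does not save money).

```bash
$ rootcea threshold rr_fluoride
rr_fluoride threshold at WTP 214: 0.510166
```

If the varnish risk ratio rose above ~0.51 (i.e. the varnish prevented
less than half the onsets it does in the base case), the ICER would
exceed the threshold.

```bash
$ rootcea psa --iterations 1000 --seed 1
cost-effective at WTP 214: 69.4%; dominant: 21.2%
```

Under joint parameter uncertainty the programme is cost-effective in
about seven of ten simulated scenarios, and actually cost-saving in
about two of ten. `rootcea tornado` writes the one-way table (the risk
ratio, the onset probability and the varnish price are the three
dominant uncertainties), and `rootcea simulate` / `rootcea estimate`
generate a synthetic exam cohort and re-estimate its probabilities.

The same API is available from Python:

```python
import rootcea as rc

cfg = rc.base_case()
ctrl = rc.run_cohort(cfg, "control")
flu = rc.run_cohort(cfg, "fluoride")
print(rc.incremental(ctrl, flu, wtp=214).icer)  # 161.16...
```

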