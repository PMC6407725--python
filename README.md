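# evomedia

Experiment-in-the-loop genetic-algorithm (GA) optimization of cell-culture
media on 96-well plates.

Optimizing a growth medium for cells with unknown nutritional requirements —
for example primary cell cultures of marine sponges — means searching a
high-dimensional space of component concentrations (here: 20 amino acids)
where factorial designs are hopeless and component interactions are unknown.
`evomedia` implements the GA approach to this problem for bioprocess
engineers: medium compositions are encoded as binary chromosomes over
discrete concentration grids, evolved by fitness-proportional selection,
single-point crossover, and bitwise mutation, and scored by a fluorescence
(resazurin-reduction) metabolic assay relative to the unmodified basal
medium. Because one generation takes days of wet-lab time, the optimizer is
driven through an ask/tell interface whose state serializes to a single JSON
file.

## The model

Each optimizable component *i* spans `[lowerᵢ, upperᵢ]` µg/ml in
`nᵢ` equal steps; its *gene* has `bᵢ = ⌈log₂(nᵢ + 1)⌉` bits and a bit code
`v` decodes to `lowerᵢ + min(v, nᵢ)·stepᵢ` (surplus codes clip to the upper
bound). The concatenated genes form the chromosome (91 bits for the packaged
20-amino-acid table, gene lengths 3–6 bits).

Fitness is the **relative increase in metabolic activity (RIMA)**: with
paired cells and cell-free plates, per replicate
`net RFU = RFU(cells) − RFU(cell-free)`, and

```
RIMA(treatment) = mean net RFU(treatment) / mean net RFU(control)
```

so RIMA > 1 means the composition outperforms the basal medium. Each
treatment is compared with the control by a two-sided equal-variance
Student's t test on net replicates (α = 0.05, uncorrected).

Selection is roulette-wheel on floored fitness; by default the wheel is
*windowed* (the generation minimum is subtracted first), which restores
selection pressure when all RIMA values sit in a narrow band around 1.
Offspring are kept unique within a generation (the plate budget of 30
treatments in triplicate plus controls fills 93 of 96 wells).

A synthetic fitness landscape (`evomedia.landscape`) closes the loop without
a wet lab: a Gaussian-bowl response `surface(x) = max_gain^(1 − d(x))` with a
planted on-grid optimum, optional pairwise interactions, per-animal
multiplicative effects, and additive replicate noise, normalized so the
control composition scores exactly 1 and the optimum exactly `max_gain`.

## Worked example

A fully simulated four-generation campaign on the packaged amino-acid table
(20 optimizable components):

```
$ evomedia init ranges.csv campaign.json --seed 7
campaign initialized: 20 optimizable components, 91-bit chromosome

$ evomedia ask campaign.json --plates plates.csv --recipes recipes.csv
generation 1: 30 treatments

$ evomedia simulate campaign.json --assay assay.csv --seed 7 --model model.json
$ evomedia score assay.csv fitness.csv
30 treatments scored; 26 improved over M199, 1 significantly (p < 0.05)

$ evomedia tell campaign.json fitness.csv
generation 1 frozen; best fitness 1.391
```

Repeating ask → simulate → score → tell three more times:

```
generation 2 frozen; best fitness 1.473; best-fitness change vs previous generation +5.9%
generation 3 frozen; best fitness 1.657; best-fitness change vs previous generation +12.5%
generation 4 frozen; best fitness 1.858; best-fitness change vs previous generation +12.2%
```

`score` reports how many treatments beat the control (RIMA > 1) and how many
do so significantly; `tell` reports the best RIMA of the frozen generation
and a stagnation metric. (At triplicate scale the per-generation best is a
noisy statistic — the generation-4 best of 1.858 on a landscape whose true
ceiling is 1.6 illustrates the winner's curse; the campaign-best *composition*
is what one carries forward.) `evomedia report` then writes per-component
convergence diagnostics: top/bottom treatment concentrations per generation
against the allowed range, envelope widths, and concentration–fitness
correlations.

In a real campaign, `simulate` is replaced by the plate reader: `ask` emits
the plate maps and per-treatment stock-volume recipes (µl of each 5 g/L
amino-acid stock, diluent make-up), and the reader's RFU export is scored by
`evomedia score`.

The same loop is available as a library: `Campaign.ask()` /
`Campaign.tell()`, with `design_plates`, `volumes_for_treatment`,
`compute_fitness`, `convergence_report`, and `recovery_experiment` for
simulation studies.

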