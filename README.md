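# cpast

Active-inference simulation of **c**ulturally **p**atterned **a**ttention
**st**yles: how the decorative complexity of artefacts shapes visual foraging,
what the forager learns from it, and how that learning transfers to a new
perceptual task.

## The problem

Archaeological eye-tracking work has found that the verticality of scanpaths
over decorated pottery tracks the decorative (and, by proxy, social) complexity
of the culture that produced it. This package implements a computational
account of that observation: a discrete-state active-inference agent forages
over synthetic "vase" stimuli — binary pigment grids decorated with motif
families of graded verticality (complexity levels 0–3, each level a superset of
the last) — and the statistics of its saccades and of its learned internal
model are read out as phenotypes of the attention style the artefact trains.

The agent carries a two-level generative model

- **A¹** — deterministic likelihood over {pigment, no-pigment} for the nine
  locations of its 3×3 fovea, *remapped* from the environment after every
  saccade (the agent never holds a global scene model);
- **A²** — P(location | motif), the normalised pigment map of each motif;
- **B¹** — deterministic level-1 transitions (a saccade re-centres the fovea);
- **B²** — column-stochastic motif-transition matrix, the only learned object:
  Dirichlet counts **b²** are incremented by `rate · q₂(t) q₂(t−1)ᵀ` once per
  inference cycle (one level-2 cycle per four level-1 steps);
- **C** — log-preferences over outcomes (pigment strongly preferred);
- **D¹, D²** — uniform initial priors.

Saccade targets are scored by a single-step expected free energy

```
G(a) = w_r · KL[ Q(o|a) ‖ softmax(C) ]  +  w_a · H[ Q(o|a) ]
       − w_n · Σⱼ q₂(j) ( 1/α_{m(a),j} − 1/α₀,j )
```

(risk + ambiguity − Dirichlet novelty of the motif transition the move would
evidence) and chosen greedily, ties broken at random.

Three statistics summarise a run:

- **vertical index** `Vi = (h·n_vert − w·n_horiz) / (h·n_vert + w·n_horiz)`
  over the bounding box (h, w) of the gazed region;
- **C-PAST entropy** `H[B²] = −Σᵢ Σⱼ B²ᵢⱼ log B²ᵢⱼ` (nats), the dispersal of
  the learned transition structure;
- **hit rate** in a transfer task: the learned B², frozen, is the prior of a
  cut-out categorisation task (match a partially occluded shape to one of the
  four motif shapes, with an aversive "+" distractor) and resolves the
  ambiguous trials.

## Worked example

```
cpast reproduce --out report
```

runs 20 foraging episodes per complexity level (100 timesteps each, grid
30×30) plus the transfer task (20 predetermined cut-out series × every trained
agent) and prints, with the default master seed:

```
vi: spearman rho = +1.000 -> PASS
cpast_entropy: spearman rho = +1.000 -> PASS
hit_rate: spearman rho = +1.000 -> PASS
```

with `report/summary.csv` containing

```
complexity  vi_mean  cpast_entropy_mean  bbox_area_mean  hit_rate_mean
0           -0.9999  4.1629               52.0           0.5983
1           -0.9859  4.3951              156.0           0.6093
2           -0.9439  4.9026              286.0           0.6199
3           -0.8238  5.4592              438.2           0.6245
```

Reading the rows: a level-0 vase (a single horizontal band) pins the agent to
one row — Vi ≈ −1, a tiny gazed area, and a learned B² that is deterministic in
its one used column (entropy 4.16 = three untouched uniform columns plus one
near-delta column). Each added motif family pulls gaze vertically (Vi rises),
widens the explored region, and disperses the learned transitions (entropy
approaches the 4·ln 4 ≈ 5.545 maximum). Agents trained on richer vases carry
less self-locked transition priors, which is exactly what the ambiguous
cut-out trials reward: hit rate climbs from 0.598 to 0.625 under the same
predetermined series.

Other commands: `cpast forage` (per-episode scanpath/heatmap/transfer files),
`cpast categorise <b2.csv>` (one transfer run from a saved matrix),
`cpast sweep` (the raw per-run tables). All outputs embed the resolved-config
hash and master seed; rerunning any command with an identical config is
byte-identical. `configs/default.yaml` lists every setting.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full default sweep from scratch (foraging across the four levels,
then the transfer task), prints the per-complexity summary table to stderr,
and writes the target-value JSON to `--out`.
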