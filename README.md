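# binlot

Minimal-description-length complexity for binary sequences, and the
behavioral machinery to race it against rival complexity metrics.

A binary sequence over `{A, B}` is described in a tiny recursive language
with two instructions — `+0` (stay) and `b` (flip) — plus repetition with
an optional silent transform applied after every repetition
(`[+0]^4<b>` emits `ABAB`) and concatenation (`,`). The cost of an
expression is a weighted sum of its instructions (weight 2, silent
transforms included) and the decimal digits of its repetition counts
(`ceil(log10 n)`, `n = 1` free). The complexity of a sequence is the cost
of its cheapest expression; the package finds that minimum *exactly* by
dynamic programming over substring spans and start/end states, returns
every tied minimal expression, and supports a chunk-preserving variant in
which repeated-block boundaries may never split a run of identical items
(no `A][A` / `B][B`).

Around that core:

- `binlot.lot` — grammar, evaluator, costs, surface notation
  (`[[+0]^8]^2<b>`), exact minimizer, brute-force enumeration oracle,
  canonical catalogs, periods.
- `binlot.metrics` — rival measures: run-based chunk complexity, pair
  entropy, LZ78 vocabulary size, subsymmetries (palindromic substrings),
  recursive-difference change complexity, and an external
  algorithmic-complexity lookup table.
- `binlot.surprise` — fixed first-order transition probabilities from one
  sequence presentation and Shannon surprise of deviant items, with 0.01
  padding of zero probabilities (cap ≈ 6.64 bits).
- `binlot.behavior` — trial classification (hit window 200–2500 ms),
  leave-one-out RT trimming at 2.5 SD around the cell median, LISAS
  (`RT_c + MR * S_RT / S_MR`), participant exclusion, per-sequence score
  tables.
- `binlot.models` — maximum-likelihood random-intercept mixed models,
  likelihood-ratio tests, Akaike weights, and the AIC/BIC model race.
- `binlot.simulate` — synthetic trial tables with known ground truth
  (linear RT / logistic miss models with participant intercepts) and
  presets mirroring the five experimental designs.
- `binlot.io` / `binlot.cli` — CSV/TSV readers and the `binlot` command.

## Command line

```bash
binlot complexity ABBAAB                 # -> complexity=5  [+0,b]^3
binlot complexity ABBAAB --chunk         # -> complexity=9
binlot metrics catalog.tsv --out metrics.csv [--acss acss.csv]
binlot surprise AAAAAAAABBBBBBBB --positions 9,11,13,15
binlot simulate --preset exp3 --seed 7 --out trials.csv --truth truth.json
binlot score trials.csv --out scores.csv
binlot race scores.csv --predictors lot,lot_chunk,chunk,entropy,lz,subsym,change \
    --out race.csv [--plot race.png]
binlot pipeline --config run.yaml        # simulate/load -> score -> race
```

Sequence catalogs are TSV with `sequence_id` and `pattern` columns; trial
tables are CSV with participant / sequence / deviant / RT / response
columns (a `column_map` stanza in the pipeline YAML adapts external
headers).

## Cost scheme derivation

The instruction weight 2 and digit weight 1 are the unique small integers
consistent with all printed values simultaneously: the 16-item
`A^nB^n` family at 6 ("2 instructions and 2 digits": 2·2 + 2·1 = 6),
`ABBAAB` at 5 (`[+0,b]^3`: 2 instructions + 1 digit), `ABAAAB` at 10
(`[+0]^2<b>,[+0]^3,b`: 4 instructions + 2 digits), `ABBAABABBAAB` at 8
(`[[+0,b]^3]^2<b>`: 3 instructions + 2 digits), and the chunk-preserving
`ABBAAB` at 9 (`+0,[b,+0]^2,b`: 4 instructions + 1 digit).
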