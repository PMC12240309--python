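# File formats

## JSON model dialect

One object with keys:

* `id`, `name`, `unit` — strings (`unit` is a label, never rescaled).
* `metabolites` — list of `{id, name, compartment, formula?, charge?}`;
  `id` is `base[compartment]` (e.g. `"ac[lu]"`) and must match
  `compartment`.
* `reactions` — list of `{id, name, stoichiometry, lower_bound,
  upper_bound, gpr, subsystem, kind}`; `stoichiometry` maps metabolite id →
  signed coefficient (negative = consumed); `kind` ∈ `internal | exchange |
  sink | demand | transport` (inferred when omitted); `gpr` is a boolean
  expression over gene ids with `and`/`or`/parentheses.
* `objective` — map reaction id → weight.

Serialization is stable: sorted keys, floats throughout, so re-writing a
loaded model is byte-identical.

## TSV tables model

A directory with `reactions.tsv` (columns `id, name, equation, lb, ub,
gpr, subsystem, kind, objective`), `metabolites.tsv` (`id, name,
compartment, formula, charge`) and `genes.tsv` (`id`). `equation` accepts
either a coefficient map `A[c]:-1;B[c]:1` or an arrow form
`2 A[c] + B[c] -> C[c]` (also `<->` and `<-`). Metabolites appearing only
in equations are created on the fly.

## SBML

SBML Level 3 + FBC v2 via cobra: bounds as parameters, GPRs as
`fbc:geneProductAssociation`, subsystems as groups. Bracketed ids are
SId-encoded (`[` → `__91__`, `]` → `__93__`) on write and decoded on read,
so round-trips preserve ids exactly.

## Other tables

* Expression: TSV, gene rows × sample columns, header row; group labels in
  a sidecar TSV (`sample, group` with labels `healthy`/`disease`).
* Tasks: TSV (`task_id, description, inputs, outputs`; semicolon-separated
  metabolite lists) or the equivalent JSON list.
* Medium/diet: TSV (`metabolite_id, uptake_bound`).
* Abundances: TSV (`taxon, relative_abundance`).
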