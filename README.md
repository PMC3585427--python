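# dendricap

Boolean computation capacity of two-stage dendritic neuron models.

## The problem

Pyramidal neurons with dendritic spikes act as two-layer networks and can
compute linearly non-separable functions such as XOR. But many neuron
classes — cerebellar stellate cells are the canonical example — have
passive dendrites where synaptic inputs sum *sub-linearly* (saturation),
and support few independent dendritic sub-units. Can such neurons still
compute linearly non-separable functions, and if so, how?

`dendricap` answers this with exact Boolean analysis of a binary two-stage
neuron model. The neuron fires when the summed sub-unit outputs reach the
somatic threshold Θ:

    y(x) = 1   iff   Σ_j D_j(w_j · x) ≥ Θ

where `x ∈ {0,1}^n` is the input vector, each `w_j` is a vector of
non-negative integer synaptic weights, and each dendritic activation `D_j`
is either

* **spiking**:    `D(s) = 0` if `s < θ`, else `h`  — supra- *and*
  sub-linear (a dendritic spike), or
* **saturating**: `D(s) = s` if `s < θ`, else `h`  — strictly sub-linear
  (passive saturation), or
* **linear** (the peri-somatic path).

Because weights are non-negative and activations non-decreasing, such
neurons compute exactly the *positive* (monotone) Boolean functions;
capacity is measured in *representative* functions — equivalence classes
under permutation of input labels.

The package provides:

* enumeration of all positive Boolean functions of `n ≤ 7` variables
  (recursive pair construction, streaming for large `n`) and their
  canonical representatives, cross-checked by order-ideal counting and
  Burnside's lemma;
* an exact integer-witness linear-separability test;
* exhaustive, memoized capacity searches over integer parameter grids for
  the purely linear model and the linear-plus-one-dendritic-sub-unit
  models;
* DNF/CNF neuron synthesis (one spiking sub-unit per prime implicant, or
  one sub-unit per prime clause), local/global strategy classification,
  and an exhaustive verification that *no* saturating parameter set
  implements the feature binding problem with a local strategy.

The central test case is the feature binding problem family on 4 inputs:
FBP `(x1∧x2)∨(x3∧x4)`, its dual dFBP `(x1∨x2)∧(x3∨x4)`, and the
overlapping-feature chain pFBP `(x1∧x2)∨(x2∧x3)∨(x3∧x4)` — exactly the
three linearly non-separable positive classes at `n = 4`.

## Worked example

Capacity of the three model conditions at `n = 4`, each searched over its
sufficient parameter ranges (`lin`: weights ≤ 3, Θ ≤ 5; `sat`: weights ≤ 2,
θ ≤ 2, h ≤ 2, Θ ≤ 4; `spk`: weights ≤ 2, θ ≤ 2, h ≤ 3, Θ ≤ 6):

```
$ dendricap report --n 4
          condition  classes  separable  non_separable
all_representatives       30         27              3
                lin       27         27              0
                spk       30         27              3
                sat       29         27              2
```

Of the 30 representative positive functions of 4 variables, the purely
linear model computes the 27 linearly separable ones. Adding a single
spiking sub-unit adds exactly the 3 non-separable classes (FBP, dFBP,
pFBP). A single saturating sub-unit also breaks the separability barrier
within these ranges (dFBP and pFBP); widening the saturating search to
weights ≤ 4, θ ≤ 4, h ≤ 4, Θ ≤ 8 recovers the FBP as well
(`dendricap capacity --n 4 --model sat --w-soma 4 --w-dend 4 --theta 4
--height 4 --soma-threshold 8`).

At `n = 5` the spiking advantage grows to 89 classes:

```
$ dendricap capacity --n 5 --model spk --table1
spk n=5: 208 classes (119 separable, 89 non-separable)
```

How a function is implemented differs qualitatively between the two
nonlinearities. Exhaustively sweeping every validated saturating parameter
set with weights ≤ 4, θ ≤ 4, h ≤ 4, Θ ≤ 8:

```
$ dendricap verify-prop3 --w-max 4 --theta-max 4 --height-max 4 --soma-max 8
saturating: 0 local, 8 global FBP implementations
no local strategy exists
```

Every saturating implementation of the FBP is *global* — no dendritic
sub-unit can trigger the soma alone; the same grid with spiking sub-units
contains local implementations. This is the finite confirmation of the
general impossibility: a strictly sub-linear unit cannot implement a
multi-variable term, so saturating dendrites admit only CNF-style
cooperative strategies.

Other subcommands: `representatives` (enumerate classes), `diff` (set
difference of two saved searches), `scan` (check range sufficiency),
`synthesize`/`classify` (DNF/CNF construction and strategy analysis),
`fixtures` (write the reference truth tables and witness neurons).

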