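# pedident

Exact relatedness coefficients in pedigrees with **inbred founders**, and
solvers that go the other way: given target coefficients, build a finite
pedigree that realises them.

Pedigree founders are conventionally assumed noninbred, which makes some
perfectly ordinary situations unrepresentable — a completely inbred lab
strain parent, or background inbreeding in a wild population, would require
an infinite mating chain.  `pedident` instead lets every founder carry an
assigned inbreeding coefficient `f ∈ [0, 1]` and computes, exactly:

- **kinship** `φ_ab` and inbreeding coefficients (recursive algorithm, plus
  Wright's path formula as an independent check);
- **generalized kinship** coefficients over up to four sampled alleles in
  one or two IBD groups (Karigl-style recursion with inbred-founder
  boundary conditions such as `φ_aaa = (1 + 3f)/4`);
- **condensed identity coefficients** `Δ1..Δ9` (Jacquard's nine states) by
  solving a fixed 9×9 linear system in the generalized coefficients, and
  the IBD triple `κ = (κ0, κ1, κ2) = (Δ9, Δ8, Δ7)` for noninbred pairs;
- **constructibility solvers**: any `φ ∈ [0,1]` as a single half-cousin
  relationship `φ = (1+f)/2^(m+1)` or as a finite chain of outbred
  half-cousin layers (binary expansion); any admissible `κ`
  (`κ1² ≥ 4κ0κ2`) as a double half cousin relationship, via
  `U = 1 + κ2 − κ0`, `D = U² − 4κ2`, `φ1,2 = (U ∓ √D)/2`; plus the induced
  subdivision of the IBD triangle into cells `A_{m,n}`;
- a **gene-dropping simulator** implementing the underlying single-locus
  model literally, used throughout the test suite as an independent oracle.

Results are exact rationals whenever founder coefficients are rational.

## Worked example

Half siblings whose shared mother has background inbreeding `f = 1/4`:

```python
from fractions import Fraction
import pedident as pdi

ped, (a, b) = pdi.standard_pedigree("half_sibs", founder_f={"M": Fraction(1, 4)})
print("kinship:", pdi.kinship(ped, a, b))
print("deltas :", [str(d) for d in pdi.condensed_identity(ped, a, b)])
print("kappa  :", [str(k) for k in pdi.ibd_triple(ped, a, b)])
```

prints

```
kinship: 5/32
deltas : ['0', '0', '0', '0', '0', '0', '0', '5/8', '3/8']
kappa  : ['3/8', '5/8', '0']
```

The mother's inbreeding raises the sibs' kinship from 1/8 to
(1+1/4)/8 = 5/32 and their one-allele sharing probability κ1 from 1/2 to
5/8; the pair itself stays noninbred (Δ1..Δ6 = 0).

Going the other way — realise the IBD coefficients of quadruple half first
cousins, `κ = (17/32, 14/32, 1/32)`, with a *different*, 12-member
pedigree:

```python
sol = pdi.ibd_to_dhc((Fraction(17, 32), Fraction(14, 32), Fraction(1, 32)))
print("solver :", sol.m, sol.n, round(sol.f1, 6), round(sol.f2, 6))
ped2, pair = pdi.build_dhc(sol)
print("rebuilt kappa:", [round(float(k), 10) for k in pdi.ibd_triple(ped2, *pair)])
```

```
solver : 3 1 0.171573 0.707107
rebuilt kappa: [0.53125, 0.4375, 0.03125]
```

The solver finds fathers that are half cousins at separation m = 3 with top
founder inbreeding f1 = 3 − 2√2, and mothers at separation n = 1 with
f2 = √2/2; computing identity coefficients on the built pedigree returns
exactly the target triple.

## Command line

```sh
pedident kinship --ped family.ped --finb family.finb --ids A B
pedident identity --ped family.ped --ids A B --kappa
pedident gkinship --ped family.ped --pattern "A,B/C,D"
pedident construct-kinship 25/64 --chain --out chain
pedident construct-ibd 17/32 14/32 1/32 --out q
pedident triangle-region 0.25 0.25
pedident genedrop --ped family.ped --ids A B --n 100000 --seed 1
```

PED files are whitespace-separated `id father mother sex` with `0` for a
missing parent; founder inbreeding lives in a two-column companion table
(`id f`, fractions or decimals).  Exit codes: 0 success, 2 invalid input,
3 violated precondition (inadmissible `κ`, inbred individual in a `κ`
computation).

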