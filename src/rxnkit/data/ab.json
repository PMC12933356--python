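{
 "schema": 1,
 "species": [
  {
   "label": "A",
   "name": "A",
   "composition": {
    "C": 1,
    "H": 2,
    "O": 1
   },
   "charge": 0
  },
  {
   "label": "B",
   "name": "B",
   "composition": {
    "C": 1,
    "H": 2,
    "O": 1
   },
   "charge": 0
  }
 ],
 "steps": [
  {
   "id": "R1",
   "reactants": {
    "A": 1
   },
   "products": {
    "B": 1
   },
   "Ga_fwd": 8.0,
   "dG": -1.0,
   "step_class": "other",
   "Ga_provenance": "supplementary",
   "dG_provenance": "supplementary"
  }
 ],
 "meta": {
  "name": "ab",
  "notes": "A<=>B; equilibrium [B]/[A] = exp(1.0/RT) ~ 4.43 at 338.15 K."
 }
}
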