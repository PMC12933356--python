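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
  },
  {
   "label": "C",
   "name": "C",
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
  },
  {
   "id": "R2",
   "reactants": {
    "B": 1
   },
   "products": {
    "C": 1
   },
   "Ga_fwd": 10.0,
   "dG": -2.0,
   "step_class": "other",
   "Ga_provenance": "supplementary",
   "dG_provenance": "supplementary"
  }
 ],
 "meta": {
  "name": "abc",
  "notes": "A<=>B<=>C chain fixture."
 }
}
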