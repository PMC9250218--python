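# Default anchor settings for type 2 diabetes: 12 complication categories,
# each with the ICD-10 codes that experts assert belong to that category
# alone.  "serial" is the 1-based category number used in published tables;
# internally categories are indexed serial - 1.
#
# The "Diabetes" category itself is anchored so that uncomplicated diabetes
# (E11.9) has a home and does not float between complication groups.
complications:
  - serial: 1
    name: "Diabetes"
    codes: ["E11.9"]
  - serial: 2
    name: "Acute complications"
    codes: ["E11.0", "E11.1", "K81", "J20"]
  - serial: 3
    name: "Cardiovascular"
    codes: ["I25", "I10"]
  - serial: 4
    name: "Nephropathy"
    codes: ["E11.2", "N18"]
  - serial: 5
    name: "Ophthalmopathy"
    codes: ["E11.3", "H26.9"]
  - serial: 6
    name: "Peripheral vascular"
    codes: ["E11.5", "I83"]
  - serial: 7
    name: "Cerebrovascular"
    codes: ["I63", "G45"]
  - serial: 8
    name: "Neuropathy"
    codes: ["E11.4", "G63.2"]
  - serial: 9
    name: "Metabolic complications"
    codes: ["E11.6", "E78"]
  - serial: 10
    name: "Tumor"
    codes: ["Z51.1", "C34", "C16"]
  - serial: 11
    name: "Musculoskeletal"
    codes: ["M48", "M13", "M81"]
  - serial: 12
    name: "Autoimmune diseases"
    codes: ["K52", "E04", "J45"]
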