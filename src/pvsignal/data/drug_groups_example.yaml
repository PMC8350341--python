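# Example drug-group configuration: 19 ATC-labelled classes covering 58
# drugs reported with gastrointestinal obstruction/perforation. ATC codes
# are labels only (no ontology logic). Celecoxib and opium intentionally
# appear in two groups each. Edit freely; matching is exact on normalized
# names unless the pipeline's match_contains option is set.
groups:
  - label: Alpha glucosidase inhibitors
    atc: A10BF
    drugs: [acarbose, miglitol, voglibose]
  - label: Antipropulsives
    atc: A07DA
    drugs: [opium, loperamide]
  - label: Barium sulfate containing X-ray contrast media
    atc: V08BA
    drugs: [barium sulfate with suspending agents]
  - label: Butyrophenone derivatives
    atc: N05AD
    drugs: [haloperidol, bromperidol, droperidol]
  - label: Coxibs
    atc: M01AH
    drugs: [celecoxib]
  - label: Dantrolene and derivatives
    atc: M03CA
    drugs: [dantrolene]
  - label: Diazepines, oxazepines, thiazepines and oxepines
    atc: N05AH
    drugs: [clozapine, olanzapine, quetiapine, asenapine]
  - label: Drugs for treatment of hyperkalemia and hyperphosphatemia
    atc: V03AE
    drugs: [polystyrene sulfonate, sevelamer, lanthanum carbonate, colestilan, ferric citrate]
  - label: Drugs for urinary frequency and incontinence
    atc: G04BD
    drugs: [flavoxate, oxybutynin, propiverine, tolterodine, solifenacin, fesoterodine, mirabegron]
  - label: Natural opium alkaloids
    atc: N02AA
    drugs: [morphine, opium, oxycodone]
  - label: Non-selective monoamine reuptake inhibitors
    atc: N06AA
    drugs: [imipramine, clomipramine, amitriptyline, nortriptyline, amoxapine, maprotiline]
  - label: Oral bowel cleanser
    atc: ""
    drugs: [sodium potassium combination]
  - label: Other antineoplastic agents
    atc: L01XX
    drugs: [asparaginase, hydroxycarbamide, estramustine, celecoxib, anagrelide, eribulin, aflibercept]
  - label: Other antipsychotics
    atc: N05AX
    drugs: [risperidone, mosapramine, zotepine, aripiprazole, paliperidone, brexpiprazole]
  - label: Phenothiazines with aliphatic side-chain
    atc: N05AA
    drugs: [chlorpromazine, levomepromazine]
  - label: Poly (ADP-ribose) polymerase (PARP) inhibitors
    atc: L01XK
    drugs: [olaparib]
  - label: Proteasome inhibitors
    atc: L01XG
    drugs: [bortezomib, ixazomib]
  - label: Topoisomerase 1 (TOP1) inhibitors
    atc: L01CE
    drugs: [irinotecan]
  - label: Vinca alkaloids and analogues
    atc: L01CA
    drugs: [vinblastine, vincristine, vindesine, vinorelbine]
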