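{
  "comment": "Published domain annotations for the human PARP family, used as regression references and as label sources for reference-based superposition. Ranges quoted directly in the literature are exact; ranges marked approximate were read off published architecture schematics and may differ by a few residues.",
  "nomenclature": {
    "HD": "PARP1-type autoinhibitory helical subdomain (PARP1/2/3/4); with ART it forms the CAT domain",
    "HE": "helical extension appended to ART in PARP6/8/16; structurally distinct from HD",
    "C4": "C4-configuration zinc finger as in the third ZnF of PARP1",
    "C4*": "structurally distinct C4-type zinc finger found in PARP6 and PARP8",
    "CCHC": "CCHC-coordination zinc finger",
    "CCCH": "CCCH-coordination zinc finger",
    "MZAP": "middle domain of ZAP: one CCCH ZnF plus two WWE domains (PARP7/12/13)",
    "NZAP": "N-terminal RNA-binding domain of ZAP (PARP12/13)",
    "MVPID": "major-vault-protein-interacting domain at the PARP4 C terminus",
    "ITIHL": "inter-alpha-trypsin heavy-chain-like region of PARP4 (contains VIT and vWA)",
    "ART": "ADP-ribosyl transferase domain",
    "ARC": "ankyrin repeat cluster (tankyrases)",
    "KH": "K-homology nucleic-acid-binding domain (type I in PARPs)",
    "RWD": "E2/UBC-related domain named after RING fingers, WD proteins, DEXDc helicases",
    "WGR": "domain named after conserved Trp-Gly-Arg residues; DNA-damage sensing in PARP1/2/3",
    "BRCT": "BRCA1 C-terminus domain",
    "WWE": "domain named after conserved Trp-Trp-Glu residues; PAR recognition",
    "Macro": "macrodomain; ADP-ribose binding",
    "RRM": "RNA recognition motif",
    "SAM": "sterile alpha motif; mediates tankyrase polymerisation",
    "UIM": "ubiquitin-interacting motif",
    "VIT": "vault protein inter-alpha-trypsin domain",
    "vWA": "von Willebrand factor type A domain"
  },
  "label_sources": {
    "WGR": {"pdb": "4DQY", "note": "PARP1 WGR in a DNA-bound multidomain structure"},
    "HD": {"pdb": "4DQY", "note": "PARP1 HD in a DNA-bound multidomain structure"},
    "ITIHL": {"pdb": "6FPY", "note": "crystal structure of the ITIH1 core region"},
    "RWD": {"pdb": "2EBM", "note": "NMR structure of the RWD domain of RWDD1"},
    "KH": {"pdb": "1J5K", "note": "hnRNP K KH domain bound to single-stranded DNA"},
    "MZAP": {"pdb": "7KZH", "note": "experimental structure of the PARP13 central ZnF+2xWWE arrangement"}
  },
  "entries": {
    "PARP1_HUMAN": {
      "length": 1014,
      "domains": [
        {"label": "ZnF1", "ranges": [[9, 93]], "approximate": true},
        {"label": "ZnF2", "ranges": [[113, 199]], "approximate": true},
        {"label": "ZnF3", "ranges": [[216, 366]], "approximate": true},
        {"label": "BRCT", "ranges": [[383, 525]], "approximate": false,
         "note": "range used for the isolated BRCT construct; includes part of the C-terminal linker"},
        {"label": "WGR", "ranges": [[542, 645]], "approximate": true},
        {"label": "HD", "ranges": [[662, 784]], "approximate": true},
        {"label": "ART", "ranges": [[785, 1014]], "approximate": true}
      ]
    },
    "PARP4_HUMAN": {
      "length": 1724,
      "domains": [
        {"label": "BRCT", "ranges": [[1, 90]], "approximate": true},
        {"label": "WGR", "ranges": [[165, 240]], "approximate": true},
        {"label": "HD", "ranges": [[250, 370]], "approximate": true},
        {"label": "ART", "ranges": [[371, 575]], "approximate": true,
         "note": "the N-terminal region (1-575) mirrors PARP1 in domain composition"},
        {"label": "ITIHL", "ranges": [[650, 1420]], "approximate": true},
        {"label": "MVPID", "ranges": [[1570, 1724]], "approximate": false}
      ]
    },
    "PARP6_HUMAN": {
      "length": 630,
      "domains": [
        {"label": "C4*", "ranges": [[284, 330]], "approximate": false},
        {"label": "RWD", "ranges": [[331, 420], [540, 570]], "approximate": true, "split": true}
      ]
    },
    "PARP8_HUMAN": {
      "length": 854,
      "domains": [
        {"label": "C4*", "ranges": [[503, 552]], "approximate": false}
      ]
    },
    "TNKS1_HUMAN": {
      "length": 1327,
      "domains": [
        {"label": "ZnF-CHCC", "ranges": [[1232, 1246]], "approximate": false,
         "note": "integrated loop ZnF within ART; not a distinct subdomain"}
      ]
    },
    "PARP7_HUMAN": {
      "length": 657,
      "features": [
        {"label": "bridging-helix", "ranges": [[404, 419]], "approximate": false,
         "note": "wedged between ART and the first WWE; part of the MZAP:ART contact"},
        {"label": "C-terminal-extension", "ranges": [[651, 657]], "approximate": false,
         "note": "completes the beta-sheet of the first WWE domain"}
      ]
    },
    "PAR10_HUMAN": {
      "length": 1025,
      "domains": [
        {"label": "ART", "ranges": [[868, 1025]], "approximate": false}
      ]
    },
    "PAR14_HUMAN": {
      "length": 1801,
      "domains": [
        {"label": "KH1-KH2", "ranges": [[316, 468]], "approximate": false},
        {"label": "WWE-ART", "ranges": [[1459, 1801]], "approximate": false}
      ]
    }
  }
}
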