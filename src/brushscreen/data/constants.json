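{
  "version": "1.0",
  "comment": "Versioned numeric constants for brushscreen. Atom-contribution tables transcribed from Wildman & Crippen (1999, J Chem Inf Comput Sci 39:868) and Ertl et al. (2000, J Med Chem 43:3714); ESOL coefficients from Delaney (2004, J Chem Inf Comput Sci 44:1000); rule thresholds from the cited drug-likeness publications; BOILED-Egg decision ellipses digitized from Daina & Zoete (2016, ChemMedChem 11:1117).",
  "atomic_weights": {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904
  },
  "crippen": {
    "C1":  [0.1441, 2.503], "C2": [0.0, 2.433], "C3": [-0.2035, 2.753],
    "C4":  [-0.2051, 2.731], "C5": [-0.2783, 5.007], "C6": [0.1551, 3.513],
    "C7":  [0.0017, 3.888], "C8": [0.08452, 2.464], "C9": [-0.1444, 2.412],
    "C10": [-0.0516, 2.488], "C11": [0.1193, 2.582], "C12": [-0.0967, 2.576],
    "C18": [0.1581, 3.35], "C21": [0.136, 3.509], "C22": [0.4619, 4.067],
    "C23": [0.5437, 3.853], "C24": [0.1893, 2.673], "C26": [0.264, 4.305],
    "N1":  [-1.019, 2.262], "N2": [-0.7096, 2.173], "N3": [-1.027, 2.827],
    "N4":  [-0.5188, 3.0], "N5": [0.08387, 1.757], "N6": [0.1836, 2.428],
    "N7":  [-0.3187, 1.839], "N8": [-0.4458, 2.819], "N9": [0.01508, 1.725],
    "N11": [-0.3239, 2.202], "N12": [-1.119, 0.0], "N13": [-0.3396, 0.2604],
    "O1":  [0.1552, 1.08], "O2": [-0.2893, 0.8238], "O3": [-0.0684, 1.085],
    "O4":  [-0.4195, 1.182], "O7": [-1.189, 0.0], "O9": [-0.1526, 0.0],
    "O10": [0.1129, 0.2215], "O11": [0.4833, 0.389], "O12": [-1.326, 0.0],
    "O6":  [-0.3339, 0.7774], "OS": [-0.1188, 0.6865],
    "S1":  [0.6482, 7.591], "S2": [-0.0024, 7.365], "S3": [0.6237, 6.691],
    "P":   [0.8612, 6.92],
    "F":   [0.4202, 1.108], "Cl": [0.6895, 5.853], "Br": [0.8456, 8.927],
    "H1":  [0.123, 1.057], "H2": [-0.2677, 1.395], "H3": [0.2142, 0.9627],
    "H4":  [0.298, 1.805], "HS": [0.1125, 1.112]
  },
  "tpsa": {
    "N_sss": 3.24, "N_sd": 12.36, "N_t": 23.79, "N_ssdd": 11.68,
    "N_dt": 13.6, "NH_ss": 12.03, "NH_d": 23.85, "NH2_s": 26.02,
    "N+_ssss": 0.0, "N+_ssd": 3.01, "N+_st": 4.36, "NH+_sss": 4.44,
    "NH+_sd": 13.97, "NH2+_ss": 16.61, "NH2+_d": 25.59, "NH3+_s": 27.64,
    "n_ar2": 12.89, "n_ar3": 4.41, "n_ar2s": 4.93, "nH_ar": 15.79,
    "n+_ar3": 4.1, "n+_ar2s": 3.88, "nH+_ar": 14.14,
    "N_ring3": 3.01, "NH_ring3": 21.94,
    "O_ss": 9.23, "O_ss_ring3": 12.53, "O_d": 17.07, "OH_s": 20.23,
    "O-_s": 23.06, "o_ar": 13.14,
    "S_ss": 25.3, "S_d": 32.09, "S_ssd": 19.21, "S_ssdd": 8.38,
    "SH_s": 38.8, "s_ar": 28.24,
    "P_sss": 13.59, "P_sd": 34.14, "P_sssd": 9.81, "PH_ssd": 23.47
  },
  "esol": {
    "intercept": 0.16, "wlogp": -0.63, "mw": -0.0062,
    "rotatable_bonds": 0.066, "aromatic_proportion": -0.74
  },
  "rules": {
    "Lipinski": {
      "allowed_violations": 1,
      "conditions": {"MW<=500": ["molecular_weight", "<=", 500],
                     "WLOGP<=5": ["wlogp", "<=", 5],
                     "HBD<=5": ["hbd", "<=", 5],
                     "HBA<=10": ["hba", "<=", 10]}
    },
    "Ghose": {
      "allowed_violations": 0,
      "conditions": {"160<=MW<=480": ["molecular_weight", "between", 160, 480],
                     "-0.4<=WLOGP<=5.6": ["wlogp", "between", -0.4, 5.6],
                     "40<=MR<=130": ["molar_refractivity", "between", 40, 130],
                     "20<=atoms<=70": ["heavy_atoms", "between", 20, 70]}
    },
    "Veber": {
      "allowed_violations": 0,
      "conditions": {"RB<=10": ["rotatable_bonds", "<=", 10],
                     "TPSA<=140": ["tpsa", "<=", 140]}
    },
    "Egan": {
      "allowed_violations": 0,
      "conditions": {"WLOGP<=5.88": ["wlogp", "<=", 5.88],
                     "TPSA<=131.6": ["tpsa", "<=", 131.6]}
    },
    "Muegge": {
      "allowed_violations": 0,
      "conditions": {"200<=MW<=600": ["molecular_weight", "between", 200, 600],
                     "-2<=WLOGP<=5": ["wlogp", "between", -2, 5],
                     "TPSA<=150": ["tpsa", "<=", 150],
                     "rings<=7": ["rings", "<=", 7],
                     "carbons>4": ["carbons", ">", 4],
                     "heteroatoms>1": ["heteroatoms", ">", 1],
                     "RB<=15": ["rotatable_bonds", "<=", 15],
                     "HBA<=10": ["hba", "<=", 10],
                     "HBD<=5": ["hbd", "<=", 5]}
    },
    "Leadlikeness": {
      "allowed_violations": 0,
      "conditions": {"250<=MW<=350": ["molecular_weight", "between", 250, 350],
                     "WLOGP<=3.5": ["wlogp", "<=", 3.5],
                     "RB<=7": ["rotatable_bonds", "<=", 7]}
    }
  },
  "bioavailability": {
    "anion_tpsa_bins": [[75, 0.85], [150, 0.56], [null, 0.11]],
    "pass": 0.55, "fail": 0.17
  },
  "boiled_egg": {
    "white": {"tpsa_center": 71.051, "wlogp_center": 2.292,
              "tpsa_semiaxis": 71.0405, "wlogp_semiaxis": 4.37},
    "yolk": {"tpsa_center": 38.117, "wlogp_center": 3.481,
             "tpsa_semiaxis": 41.0305, "wlogp_semiaxis": 2.7785}
  }
}
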