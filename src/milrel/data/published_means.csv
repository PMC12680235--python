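dataset,model,family,mi,spearman,auprc,auc,f1,flops_m,size_k
CAMELYON16,ABMIL,ABMIL,0.12,0.29,0.59,0.85,0.84,94,789
CAMELYON16,CLAM,CLAM,0.12,0.29,0.59,0.86,0.85,94,791
CAMELYON16,DTFD,DTFD,0.13,0.29,0.61,0.89,0.85,126,1053
CAMELYON16,ACMIL/2,ACMIL,0.16,0.34,0.59,0.82,0.81,94,791
CAMELYON16,MADMIL/2,MADMIL,0.13,0.31,0.61,0.86,0.85,79,658
CAMELYON16,MAX-POOL,MAX-POOL,0.00,-0.00,0.23,0.80,0.79,63,526
CAMELYON16,MEAN-POOL,MEAN-POOL,,,,0.58,0.59,63,526
CAMELYON16,ABMIL-ADD-ATT,ABMIL-ADD-ATT,0.13,0.32,0.62,0.86,0.83,95,789
CAMELYON16,ABMIL-ADD-PATCH,ABMIL-ADD-PATCH,0.04,0.24,0.48,,,,
CAMELYON16,CLAM-ADD-ATT,CLAM-ADD-ATT,0.12,0.29,0.60,0.87,0.83,95,791
CAMELYON16,CLAM-ADD-PATCH,CLAM-ADD-PATCH,0.03,0.24,0.48,,,,
CAMELYON16,DTFD-PATCH,DTFD-PATCH,0.04,0.29,0.53,0.89,0.85,126,1053
CAMELYON16,ACMIL/2-ADD-ATT,ACMIL-ADD-ATT,0.17,0.35,0.62,0.79,0.81,95,791
CAMELYON16,ACMIL/2-ADD-PATCH,ACMIL-ADD-PATCH,0.03,-0.03,0.29,,,,
CAMELYON16,MAX-POOL-INS,MAX-POOL-INS,0.00,0.05,0.20,0.77,0.76,63,526
CAMELYON16,MAX-POOL-INS-PATCH,MAX-POOL-INS-PATCH,0.15,0.29,0.55,,,,
CAMELYON16,MEAN-POOL-INS,MEAN-POOL-INS,0.31,0.53,0.78,0.58,0.59,63,526
CATCH,ABMIL,ABMIL,0.30,0.53,0.91,0.99,0.90,94,791
CATCH,CLAM,CLAM,0.32,0.54,0.91,0.99,0.88,94,798
CATCH,DTFD,DTFD,0.20,0.56,0.91,1.00,0.93,126,1842
CATCH,ACMIL/4,ACMIL,0.28,0.55,0.92,1.00,0.93,95,807
CATCH,MADMIL/2,MADMIL,0.30,0.55,0.92,0.99,0.90,79,660
CATCH,MAX-POOL,MAX-POOL,0.00,-0.05,0.65,1.00,0.94,63,528
CATCH,MEAN-POOL,MEAN-POOL,,,,0.98,0.81,63,528
CATCH,ABMIL-ADD-ATT,ABMIL-ADD-ATT,0.29,0.53,0.90,0.98,0.90,95,791
CATCH,ABMIL-ADD-PATCH,ABMIL-ADD-PATCH,0.06,0.35,0.83,,,,
CATCH,CLAM-ADD-ATT,CLAM-ADD-ATT,0.31,0.53,0.90,0.98,0.89,95,799
CATCH,CLAM-ADD-PATCH,CLAM-ADD-PATCH,0.07,0.35,0.83,,,,
CATCH,DTFD-PATCH,DTFD-PATCH,0.09,0.42,0.87,1.00,0.93,126,1842
CATCH,ACMIL/4-ADD-ATT,ACMIL-ADD-ATT,0.23,0.55,0.91,0.99,0.92,95,806
CATCH,ACMIL/4-ADD-PATCH,ACMIL-ADD-PATCH,0.17,0.44,0.88,,,,
CATCH,MAX-POOL-INS,MAX-POOL-INS,0.00,0.00,0.66,0.99,0.89,63,528
CATCH,MAX-POOL-INS-PATCH,MAX-POOL-INS-PATCH,0.29,0.47,0.88,,,,
CATCH,MEAN-POOL-INS,MEAN-POOL-INS,0.32,0.45,0.85,0.98,0.81,63,528
TCGA_BRCA,ABMIL,ABMIL,0.19,0.44,0.82,0.95,0.85,94,789
TCGA_BRCA,CLAM,CLAM,0.18,0.48,0.84,0.95,0.84,94,791
TCGA_BRCA,DTFD,DTFD,0.15,0.47,0.84,0.96,0.87,126,1053
TCGA_BRCA,ACMIL/3,ACMIL,0.22,0.49,0.85,0.96,0.85,95,792
TCGA_BRCA,MADMIL/3,MADMIL,0.22,0.49,0.85,0.97,0.85,74,615
TCGA_BRCA,MAX-POOL,MAX-POOL,0.00,-0.06,0.61,0.93,0.80,63,526
TCGA_BRCA,MEAN-POOL,MEAN-POOL,,,,0.98,0.86,63,526
TCGA_BRCA,ABMIL-ADD-ATT,ABMIL-ADD-ATT,0.19,0.41,0.81,0.91,0.80,95,789
TCGA_BRCA,ABMIL-ADD-PATCH,ABMIL-ADD-PATCH,0.07,0.33,0.80,,,,
TCGA_BRCA,CLAM-ADD-ATT,CLAM-ADD-ATT,0.14,0.48,0.84,0.92,0.79,95,791
TCGA_BRCA,CLAM-ADD-PATCH,CLAM-ADD-PATCH,0.06,0.29,0.79,,,,
TCGA_BRCA,DTFD-PATCH,DTFD-PATCH,0.07,0.29,0.79,0.96,0.87,126,1053
TCGA_BRCA,ACMIL/3-ADD-ATT,ACMIL-ADD-ATT,0.12,0.23,0.73,0.94,0.84,95,792
TCGA_BRCA,ACMIL/3-ADD-PATCH,ACMIL-ADD-PATCH,0.06,0.11,0.70,,,,
TCGA_BRCA,MAX-POOL-INS,MAX-POOL-INS,0.00,0.01,0.61,0.89,0.73,63,526
TCGA_BRCA,MAX-POOL-INS-PATCH,MAX-POOL-INS-PATCH,0.24,0.45,0.84,,,,
TCGA_BRCA,MEAN-POOL-INS,MEAN-POOL-INS,0.27,0.30,0.79,0.98,0.85,63,526
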