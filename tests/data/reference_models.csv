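extractor,classifier,batch_size,model,kappa,accuracy,sen,spe,ppv,npv
ResNet101,NB,5,M53,0.71,0.86,0.87,0.84,0.84,0.87
AlexNet,NB,11,M7,0.65,0.83,0.81,0.84,0.83,0.82
ResNet101,NB,14,M56,0.65,0.83,0.81,0.84,0.83,0.82
AlexNet,NB,5,M5,0.62,0.81,0.77,0.84,0.83,0.79
VGG16,NB,14,M80,0.62,0.81,0.77,0.84,0.83,0.79
DenseNet201,SVM,11,M23,0.62,0.81,0.68,0.94,0.91,0.75
ResNet101,NB,8,M54,0.59,0.79,0.9,0.69,0.74,0.88
VGG19,NB,11,M91,0.59,0.79,0.84,0.75,0.77,0.83
AlexNet,NB,14,M8,0.59,0.79,0.81,0.78,0.78,0.81
DenseNet201,SVM,5,M21,0.59,0.79,0.74,0.84,0.82,0.77
DenseNet201,SVM,14,M24,0.59,0.79,0.77,0.81,0.8,0.79
VGG16,NB,8,M78,0.59,0.79,0.77,0.81,0.8,0.79
AlexNet,NB,8,M6,0.59,0.79,0.71,0.88,0.85,0.76
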