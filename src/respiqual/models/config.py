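"""Shared hyperparameter containers for model training and adaptation."""

from __future__ import annotations

from dataclasses import dataclass

from ..core import ValidationError


@dataclass(frozen=True)
class CnnHyper:
    """Training hyperparameters for the 1-D CNN (Adam, cross-entropy)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    val_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValidationError("positive learning rate, batch size and epochs required")


@dataclass(frozen=True)
class AdaptationConfig:
    """Transfer-learning knobs.

    For the SVM, ``svm_c_a`` is the box constraint on the learned
    perturbation of the source decision function: as it goes to zero the
    adapted model collapses onto the source model.  For the CNN, stage 1
    retrains only the classification layer; the optional fine-tuning stage
    un-freezes everything at a lower learning rate for a few epochs.
    """

    svm_c_a: float = 1.0
    stage1_epochs: int = 30
    stage1_lr: float = 1e-3
    finetune_epochs: int = 5
    finetune_lr: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.svm_c_a <= 0:
            raise ValidationError("svm_c_a must be positive")
        if self.stage1_epochs <= 0 or self.stage1_lr <= 0:
            raise ValidationError("positive stage-1 rate and epoch count required")
        if self.finetune_epochs < 0 or self.finetune_lr < 0:
            raise ValidationError("fine-tuning rate and epochs must be non-negative")
        if self.finetune_lr >= self.stage1_lr:
            raise ValidationError("fine-tuning learning rate must be below the stage-1 rate")
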